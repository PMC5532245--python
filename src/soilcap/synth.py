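"""Synthetic land-cover and soil-sample generation.

Emulates the structure of the real inputs at toy scale so the whole pipeline
is testable without external data, and so the estimators can be validated by
parameter recovery:

* spatially patchy categorical land-cover grids evolving under a known
  per-cell Markov transition matrix (a CORINE-like change process);
* per-cover soil-sample distributions (SOC lognormal — non-negative and
  right-skewed, with tree-covered soils parameterised highest; pH truncated
  normal on (3, 10), with crops near-neutral and woodland acidic);
* a spatially smooth peat-probability surface.

Soil properties are drawn independently given cover (no residual spatial
correlation) — a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .condition import SoilSample
from .grids import NODATA, LandCoverGrid
from .nomenclature import SEEA_CODES


@dataclass(frozen=True)
class TransitionMatrix:
    """14x14 per-cell class-transition probabilities (rows = source class)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (14, 14):
            raise ValueError(f"transition matrix must be 14x14, got {p.shape}")
        if (p < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        sums = p.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError(f"rows must sum to 1 within 1e-12; sums: {sums}")
        object.__setattr__(self, "probs", p)

    @classmethod
    def identity(cls) -> "TransitionMatrix":
        return cls(np.eye(14))

    @classmethod
    def from_changes(cls, changes: dict[tuple[int, int], float]) -> "TransitionMatrix":
        """Identity matrix perturbed by {(from_code, to_code): prob} entries."""
        p = np.eye(14)
        for (i, j), q in changes.items():
            p[i - 1, j - 1] += q
            p[i - 1, i - 1] -= q
        return cls(p)


@dataclass
class CoverDistributionParams:
    """Per-cover parameters of the soil-sample distributions.

    soc_log_mean/soc_log_sd parameterise a lognormal on SOC g/kg; ph_mean and
    ph_sd a normal truncated to (3, 10); peat_prob is the Bernoulli
    probability of the map-peat flag.
    """

    soc_log_mean: dict[int, float]
    soc_log_sd: dict[int, float]
    ph_mean: dict[int, float]
    ph_sd: dict[int, float]
    peat_prob: dict[int, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.soc_log_sd.values()) or any(
            v <= 0 for v in self.ph_sd.values()
        ):
            raise ValueError("distribution sds must be > 0")
        if any(not (0 <= v <= 1) for v in self.peat_prob.values()):
            raise ValueError("peat probabilities must lie in [0, 1]")

    @classmethod
    def default(cls) -> "CoverDistributionParams":
        # medians (g/kg): tree-covered and aquatic soils carbon-rich, cropped
        # and barren soils carbon-poor; pH: crops near-neutral, grassland
        # moderately acid, woodland and shrub acidic, barren/coastal alkaline
        soc_median = {
            1: 15, 2: 15, 3: 12, 4: 16, 5: 28, 6: 40, 7: 60,
            8: 30, 9: 80, 10: 20, 11: 6, 12: 5, 13: 12, 14: 10,
        }
        ph_mean = {
            1: 6.6, 2: 6.8, 3: 7.0, 4: 6.5, 5: 5.6, 6: 4.8, 7: 6.5,
            8: 5.2, 9: 5.5, 10: 6.4, 11: 7.4, 12: 6.0, 13: 6.5, 14: 7.6,
        }
        peat = {c: 0.01 for c in SEEA_CODES}
        peat.update({5: 0.04, 6: 0.05, 8: 0.04, 9: 0.30})
        return cls(
            soc_log_mean={c: float(np.log(m)) for c, m in soc_median.items()},
            soc_log_sd={c: 0.6 for c in SEEA_CODES},
            ph_mean=ph_mean,
            ph_sd={c: 0.6 for c in SEEA_CODES},
            peat_prob=peat,
        )


@dataclass
class SyntheticScenario:
    """Everything needed to regenerate a synthetic study deterministically."""

    shape: tuple[int, int] = (100, 100)
    cell_area: float = 0.01  # km² (100 m cells)
    n_epochs: int = 2
    epoch_labels: tuple[str, ...] = ()
    seed: int = 0
    mixture: dict[int, float] = field(default_factory=lambda: {2: 0.5, 6: 0.5})
    patchiness: float = 1.0  # expected patch diameter in cells
    transitions: TransitionMatrix = field(default_factory=TransitionMatrix.identity)
    cover_params: CoverDistributionParams = field(
        default_factory=CoverDistributionParams.default
    )
    n_samples: int = 500

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions must sum to 1, got {total}")
        if not self.epoch_labels:
            self.epoch_labels = tuple(f"epoch{i}" for i in range(self.n_epochs))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        kwargs = {}
        for key in ("cell_area", "n_epochs", "seed", "patchiness", "n_samples"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "shape" in cfg:
            kwargs["shape"] = tuple(cfg["shape"])
        if "epoch_labels" in cfg:
            kwargs["epoch_labels"] = tuple(cfg["epoch_labels"])
        if "mixture" in cfg:
            kwargs["mixture"] = {int(k): float(v) for k, v in cfg["mixture"].items()}
        if "transitions" in cfg:
            changes = {
                (int(e["from"]), int(e["to"])): float(e["prob"]) for e in cfg["transitions"]
            }
            kwargs["transitions"] = TransitionMatrix.from_changes(changes)
        return cls(**kwargs)


def eu25_toy_scenario(seed: int = 0, shape: tuple[int, int] = (150, 150)) -> SyntheticScenario:
    """A toy-scale scenario echoing the EU-25 situation: dominant herbaceous
    crops and tree cover, a small artificial class growing at the crops'
    expense, and modest woodland expansion."""
    mixture = {
        1: 0.03, 2: 0.30, 3: 0.03, 4: 0.12, 5: 0.12, 6: 0.28,
        8: 0.04, 9: 0.02, 10: 0.005, 11: 0.002, 13: 0.045, 14: 0.008,
    }
    mixture[12] = 1.0 - sum(mixture.values())  # trace of snow/ice
    tm = TransitionMatrix.from_changes(
        {
            (2, 1): 0.006,  # urban sprawl onto arable
            (2, 3): 0.001,
            (2, 6): 0.002,  # afforestation
            (5, 1): 0.002,
            (5, 6): 0.002,
            (8, 6): 0.003,
            (4, 2): 0.002,
            (10, 11): 0.002,
        }
    )
    return SyntheticScenario(
        shape=shape,
        n_epochs=3,
        epoch_labels=("2000", "2006", "2012"),
        seed=seed,
        mixture=mixture,
        patchiness=4.0,
        transitions=tm,
        n_samples=2000,
    )


def gen_initial_grid(scenario: SyntheticScenario) -> LandCoverGrid:
    """Spatially patchy categorical grid matching the scenario mixture.

    With patchiness <= 1, cells are iid multinomial draws (the per-class
    share then lies within 3 binomial standard errors of the mixture). For
    larger patchiness d, ~ncells/d² nuclei are placed at random, classes are
    drawn iid per nucleus, and each cell takes the class of its nearest
    nucleus, producing Voronoi patches of expected diameter ~d cells.
    """
    nrows, ncols = scenario.shape
    if nrows < 1 or ncols < 1:
        raise ValueError(f"degenerate grid shape {scenario.shape}")
    rng = np.random.default_rng(scenario.seed)
    classes = np.array(sorted(scenario.mixture), dtype=np.int64)
    probs = np.array([scenario.mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    n = nrows * ncols
    if scenario.patchiness <= 1:
        codes = rng.choice(classes, size=n, p=probs).reshape(nrows, ncols)
    else:
        k = max(len(classes), int(round(n / scenario.patchiness**2)))
        nuclei = rng.choice(n, size=min(k, n), replace=False)
        pts = np.stack(np.unravel_index(nuclei, (nrows, ncols)), axis=1).astype(float)
        nucleus_class = rng.choice(classes, size=len(pts), p=probs)
        rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        cells = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        _, nearest = cKDTree(pts).query(cells, k=1)
        codes = nucleus_class[nearest].reshape(nrows, ncols)
    return LandCoverGrid(
        codes, scenario.cell_area, epoch=scenario.epoch_labels[0], nomenclature="seea"
    )


def advance_epoch(
    grid: LandCoverGrid, tm: TransitionMatrix, seed: int, epoch: str = ""
) -> LandCoverGrid:
    """Redraw each cell's class independently from its row of the transition
    matrix. Nodata cells are untouched."""
    if grid.nomenclature != "seea":
        raise ValueError("advance_epoch expects a SEEA grid")
    rng = np.random.default_rng(seed)
    codes = grid.codes.copy()
    all_codes = np.arange(1, 15)
    for c in sorted(np.unique(codes)):
        if c == NODATA:
            continue
        idx = np.nonzero(codes == c)
        row = tm.probs[c - 1]
        codes[idx] = rng.choice(all_codes, size=len(idx[0]), p=row)
    return LandCoverGrid(codes, grid.cell_area, epoch=epoch, nomenclature="seea")


def simulate_epochs(scenario: SyntheticScenario) -> list[LandCoverGrid]:
    """Initial grid plus n_epochs − 1 Markov steps, all seeded from the scenario."""
    grids = [gen_initial_grid(scenario)]
    for i in range(1, scenario.n_epochs):
        grids.append(
            advance_epoch(
                grids[-1],
                scenario.transitions,
                seed=scenario.seed + i,
                epoch=scenario.epoch_labels[i],
            )
        )
    return grids


def gen_peat_probability(
    shape: tuple[int, int], seed: int, correlation_length: float = 5.0
) -> np.ndarray:
    """Smooth random peat-probability surface in [0, 1].

    Gaussian-filtered white noise rescaled to the unit interval; the
    correlation length (in cells) sets the smoothing radius.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length)
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (smooth - lo) / (hi - lo)


def gen_soil_samples(
    grid: LandCoverGrid,
    n: int,
    params: CoverDistributionParams | None = None,
    seed: int = 0,
) -> list[SoilSample]:
    """Draw n topsoil samples at distinct classified cells.

    SOC ~ lognormal, pH ~ normal truncated to (3, 10), peat ~ Bernoulli, with
    parameters taken from the sampled cell's cover class.
    """
    params = params or CoverDistributionParams.default()
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    classified = np.flatnonzero(grid.codes.ravel() != NODATA)
    if n > classified.size:
        raise ValueError(
            f"requested {n} samples but grid has only {classified.size} classified cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(classified, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, grid.shape)
    samples: list[SoilSample] = []
    for i in range(n):
        c = int(grid.codes[rows[i], cols[i]])
        soc = float(rng.lognormal(params.soc_log_mean[c], params.soc_log_sd[c]))
        mu, sd = params.ph_mean[c], params.ph_sd[c]
        a, b = (3.0 - mu) / sd, (10.0 - mu) / sd
        ph = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        peat = bool(rng.random() < params.peat_prob[c])
        samples.append(
            SoilSample(
                sample_id=f"s{i:05d}", row=int(rows[i]), col=int(cols[i]),
                cover=c, soc=soc, ph=ph, peat=peat,
            )
        )
    return samples


def recover_transitions(grid_t0: LandCoverGrid, grid_t1: LandCoverGrid) -> np.ndarray:
    """Estimate the transition matrix from an epoch pair.

    Row-normalised per-cell change tally; rows of classes absent at t0 are
    NaN (absent, not zero-filled).
    """
    from .extent import change_matrix

    cm = change_matrix(grid_t0, grid_t1, min_mapping_unit=0.0)
    flows = cm.flows.to_numpy()
    row_sums = flows.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = flows / row_sums
    est[row_sums.ravel() == 0, :] = np.nan
    return est
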