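# EU-25 extent-account inputs, 2000-2012: published opening areas (km²) and
# per-class net changes (km²). Mangrove (7) is absent from the territory and
# Permanent snow and glaciers (12) carries no published value; both are NA.
# The 410,037 km² opening is assigned to class 4 (its -2,921 reduction matches
# the published class-4 closing 407,116).
seea_code,opening_km2,net_change_km2
1,99128,8354
2,941477,-8676
3,88041,1596
4,410037,-2921
5,383142,-1228
6,1270472,4049
7,NA,0
8,143195,-1186
9,76508,-565
10,17298,-74
11,5054,-182
12,NA,0
13,155996,815
14,2106,19
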