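# EU-25 per-class soil-account inputs: areas implied by the formation cells
# (mass / 1.4 t/ha) and gross rill+sheet erosion rates (gross mass / area).
seea_code,area_ha,gross_rate_t_per_ha
2,110464899.2857143,2.6700002978968254
3,10298530.0,9.46922133547215
4,46644861.42857143,4.210552695086333
5,47646651.42857143,2.5749146754609287
6,158061822.14285716,0.22709070105213938
8,17012480.714285716,3.8668851477232695
10,3786063.571428572,40.75816665217114
11,117404.28571428572,20.90195417543774
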