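target,source,s_value_Gy_per_GBq_h
kidneys,kidneys,0.2866274247
kidneys,liver,0.0012762542
kidneys,red_marrow,0.0006381271
kidneys,spleen,0.0009571906
kidneys,total_body,0.0042465866
liver,kidneys,0.0002996859
liver,liver,0.0452695288
liver,red_marrow,0.0001997906
liver,spleen,9.98953e-05
liver,total_body,0.0019387796
red_marrow,kidneys,0.0003407143
red_marrow,liver,0.0006814286
red_marrow,red_marrow,0.0770303571
red_marrow,spleen,0.0002555357
red_marrow,total_body,0.0028126789
spleen,kidneys,0.0015639344
spleen,liver,0.0020852459
spleen,red_marrow,0.0008340984
spleen,spleen,0.4677934426
spleen,total_body,0.0052063678
total_body,kidneys,0.0013000543
total_body,liver,0.0013000543
total_body,red_marrow,0.0013000543
total_body,spleen,0.0013000543
total_body,total_body,0.0013000543
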