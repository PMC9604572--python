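case,surgery,pct_under,pct_in,pct_over,pct_map_lt65,pct_clv_active,rate_changes_per_min,total_dose_ug,mean_rate_ug_min
1,Cystectomy,3.6,89.1,7.3,0,9,4.7,1616,6.8
2,Liver surgery,0.6,95.6,3.8,0.1,94.5,4.9,1533,9.6
3,Gastrectomy,1.8,96.2,2,0,98.4,4.8,2325,5.2
4,Liver surgery,1.8,93.8,4.4,0,96.0,5.0,1240,11.7
5,Cystectomy,0.8,97.9,1.2,0,99.8,4.5,2604,6.5
6,Nephrectomy,4.1,84.4,11.5,0.5,88.6,4.3,3099,2.4
7,Pancreatectomy,3.2,86.4,10.4,0,86.1,4.8,487,3.7
8,Liver surgery,3.7,90.4,5.9,0,94.6,4.5,926,4.5
9,Pancreatectomy,0.9,90.9,8.2,0,90.1,5.0,1074,15.3
10,Pancreatectomy,1.7,97.7,0.6,0,99.6,4.9,7678,6.1
11,Colorectal surgery,4.2,90.9,4.9,0,97.6,4.5,1387,1.9
12,Nephrectomy,0,96.4,3.6,0,89.5,4.7,396,6.8
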