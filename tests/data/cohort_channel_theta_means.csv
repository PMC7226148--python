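channel,condition,theta_power
F3,baseline_pre,1.30
F3,low,1.97
F3,medium,2.20
F3,high,2.21
F3,baseline_post,1.31
F4,baseline_pre,1.76
F4,low,2.90
F4,medium,3.22
F4,high,3.32
F4,baseline_post,1.82
T3,baseline_pre,1.68
T3,low,2.36
T3,medium,2.56
T3,high,2.68
T3,baseline_post,1.71
T4,baseline_pre,1.50
T4,low,1.78
T4,medium,1.99
T4,high,2.05
T4,baseline_post,1.53
O1,baseline_pre,2.38
O1,low,3.01
O1,medium,3.26
O1,high,3.39
O1,baseline_post,2.40
O2,baseline_pre,2.47
O2,low,2.94
O2,medium,3.23
O2,high,3.34
O2,baseline_post,2.46
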