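age,theta,theta_lower,theta_upper,alpha,mu,nu
25-29,0.168740,0.153844,0.183636,1.6,15.5,36.8
30-34,0.164060,0.149164,0.178956,1.6,15.5,36.8
35-39,0.159380,0.144484,0.174276,1.6,15.5,36.8
40-44,0.154700,0.139804,0.169596,1.6,15.5,36.8
45-49,0.150020,0.135124,0.164916,1.6,15.5,36.8
50-54,0.145340,0.130444,0.160236,1.6,15.5,36.8
55-59,0.140660,0.125764,0.155556,1.6,15.5,36.8
60-64,0.135980,0.121084,0.150876,1.6,15.5,36.8
65-69,0.131300,0.116404,0.146196,1.6,15.5,36.8
70-74,0.126620,0.111724,0.141516,1.6,15.5,36.8
75-79,0.121940,0.107044,0.136836,1.6,15.5,36.8
80+,0.117260,0.102364,0.132156,1.6,15.5,36.8
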