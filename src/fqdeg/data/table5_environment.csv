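name,ploec,ploec_change,logkow,logkow_change,logt12,logt12_change,is_parent
MOX,8.869,,0.950,,1.975,,1
Derivative-1,7.978,-10.05,0.211,-77.79,0.965,-51.14,0
Derivative-2,8.163,-7.96,0.541,-43.05,0.921,-53.37,0
Derivative-3,8.389,-5.41,1.147,20.74,1.07,-45.82,0
Derivative-4,8.343,-5.93,1.258,32.42,1.094,-44.61,0
Derivative-5,8.437,-4.87,1.497,57.58,1.117,-43.44,0
Derivative-6,8.537,-3.74,1.547,62.84,1.153,-41.62,0
Derivative-7,8.467,-4.53,1.643,72.95,1.156,-41.47,0
Derivative-8,8.373,-5.59,1.102,16.00,1.068,-45.92,0
Derivative-9,8.549,-3.61,0.912,-4.00,-0.582,-129.47,0
Derivative-10,8.808,-0.69,0.453,-52.32,-0.219,-111.09,0
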