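area,site,lon,lat,c,n,p
I,1,125.60,50.15,1.33,0.85,2.17
I,2,125.62,48.46,0.87,0.56,1.27
I,3,125.56,46.64,0.43,0.24,0.84
I,4,125.45,45.23,0.68,0.58,0.99
II,5,120.20,40.41,0.96,0.53,1.23
II,6,122.95,42.00,0.76,0.49,1.14
II,7,124.79,41.33,0.37,0.24,0.57
II,8,121.44,38.91,0.96,0.53,1.23
III,9,125.97,41.94,2.13,0.49,1.14
III,10,120.07,43.63,1.42,0.88,1.36
III,11,127.55,42.82,1.23,0.72,0.99
III,12,130.71,44.47,2.13,1.15,2.17
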