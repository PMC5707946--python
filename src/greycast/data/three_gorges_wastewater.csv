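year,W1_raw,W1,W2,W3,W4
2008,5.58,5.58,5.93,41.20,404.6
2009,4.86,5.10,6.23,41.30,399.7
2010,3.19,4.00,6.15,48.13,400.5
2011,1.91,3.04,7.06,49.59,388.9
2012,1.73,2.69,7.31,51.02,397.1
2013,1.90,2.61,7.87,50.00,393.8
2014,2.12,2.12,7.94,43.90,374.0
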