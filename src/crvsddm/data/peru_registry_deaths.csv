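year,sex,minsa,reniec
2005,female,41052,47739
2005,male,47652,55468
2005,total,88704,103207
2006,female,38117,48709
2006,male,44503,56365
2006,total,82620,105074
2007,female,40411,48937
2007,male,47084,58312
2007,total,87496,107249
2008,female,42279,49184
2008,male,49011,58916
2008,total,91290,108100
2009,female,44238,50847
2009,male,51483,59964
2009,total,95722,110811
2010,female,45936,49963
2010,male,53398,58215
2010,total,99334,108178
2011,female,44669,54516
2011,male,52183,63940
2011,total,96852,118456
2012,female,45266,55536
2012,male,52720,64116
2012,total,97989,119652
2013,female,45794,58173
2013,male,52822,67408
2013,total,98616,125581
2014,female,44673,61363
2014,male,51787,71467
2014,total,96460,132830
2015,female,44643,62850
2015,male,51597,72008
2015,total,96240,134858
2016,female,45310,67721
2016,male,51918,77800
2016,total,97241,145521
2017,female,57192,70011
2017,male,63950,80021
2017,total,121142,150032
2018,female,58952,70766
2018,male,66638,80924
2018,total,125590,151690
2019,female,53107,72354
2019,male,61332,82067
2019,total,114449,154421
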