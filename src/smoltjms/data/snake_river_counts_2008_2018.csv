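population,year,Rel,Live,Dead,SAR_count
steelhead,2008,53155,50934,6822,1481
steelhead,2009,89445,100983,12467,1404
steelhead,2010,45348,29304,5318,615
steelhead,2011,80903,86392,6427,606
steelhead,2012,78040,74315,5085,1336
steelhead,2013,42953,25868,2859,514
steelhead,2014,64725,47813,5285,799
steelhead,2015,40715,16950,3198,98
steelhead,2016,79262,66351,3783,
steelhead,2017,75019,57734,3744,
steelhead,2018,64312,52118,2445,
yearling_chinook,2008,156901,131520,4336,2471
yearling_chinook,2009,167925,160002,8246,1706
yearling_chinook,2010,136085,79256,4501,803
yearling_chinook,2011,134728,136283,3208,714
yearling_chinook,2012,96343,93182,1439,1831
yearling_chinook,2013,42410,30711,649,543
yearling_chinook,2014,75662,69988,1896,483
yearling_chinook,2015,27792,12472,1046,118
yearling_chinook,2016,102858,97031,1348,
yearling_chinook,2017,56829,42363,445,
yearling_chinook,2018,47222,34233,330,
subyearling_chinook,2008,22032,12284,469,342
subyearling_chinook,2009,21347,12705,444,76
subyearling_chinook,2010,21075,14605,314,309
subyearling_chinook,2011,36537,19296,596,604
subyearling_chinook,2012,25286,12486,429,318
subyearling_chinook,2013,2529,1132,47,30
subyearling_chinook,2014,3009,1859,68,15
subyearling_chinook,2015,3718,980,39,
subyearling_chinook,2016,5203,1694,32,
subyearling_chinook,2017,5251,2386,26,
subyearling_chinook,2018,4364,2544,61,
sockeye,2008,298,265,17,2
sockeye,2009,3009,2407,111,45
sockeye,2010,1656,806,58,9
sockeye,2011,8250,4543,169,26
sockeye,2012,4322,3326,113,16
sockeye,2013,5521,2336,92,120
sockeye,2014,1656,837,69,14
sockeye,2015,1019,331,16,2
sockeye,2016,1721,823,14,1
sockeye,2017,451,170,5,
sockeye,2018,3317,1440,59,
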