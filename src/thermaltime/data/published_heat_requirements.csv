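site,season,budbreak_bloom_gdd,budbreak_bloom_days,bloom_harvest_gdd,bloom_harvest_days,total_gdd,total_days
open_field,2003,679,62,974,59,1652,121
open_field,2005,628,52,862,52,1490,104
open_field,2006,620,54,1120,68,1740,122
open_field,2007,703,65,932,55,1634,120
open_field,2008,841,71,808,48,1650,119
greenhouse,2005,574,64,924,69,1498,133
greenhouse,2006,641,64,984,68,1625,132
greenhouse,2007,613,58,929,70,1542,128
greenhouse,2008,590,58,913,70,1503,128
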