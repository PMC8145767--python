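season,observed,requirement_gdd,predicted_gdd,deviation_gdd,cycle_days,predicted_calendar,deviation_calendar
2005,2005-06-02,1498,2005-06-05,3,133,2005-05-30,-3
2006,2006-06-06,1625,2006-05-30,-7,132,2006-06-04,-2
2007,2007-06-05,1542,2007-06-05,0,128,2007-06-07,2
2008,2008-05-29,1503,2008-06-01,3,128,2008-05-31,2
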