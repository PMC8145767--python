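site,season,observed,predicted_gdd,deviation_gdd,predicted_calendar,deviation_calendar
open_field,2003,2003-07-11,2003-07-10,-1,2003-07-07,-4
open_field,2005,2005-07-03,2005-07-11,8,2005-07-16,13
open_field,2006,2006-07-10,2006-07-04,-6,2006-07-05,-5
open_field,2007,2007-07-09,2007-07-09,0,2007-07-06,-3
open_field,2008,2008-07-14,2008-07-14,0,2008-07-12,-2
greenhouse,2005,2005-06-02,2005-06-12,10,2005-05-17,-16
greenhouse,2006,2006-06-06,2006-06-07,1,2006-05-21,-16
greenhouse,2007,2007-06-05,2007-06-11,6,2007-05-25,-11
greenhouse,2008,2008-05-29,2008-06-06,8,2008-05-18,-11
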