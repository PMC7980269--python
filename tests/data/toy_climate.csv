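site_id,year,month,tmean_c,prcp_mm,latitude
A,2000,1,12.0,30.0,35.0
A,2000,2,12.0,30.0,35.0
A,2000,3,12.0,30.0,35.0
A,2000,4,12.0,30.0,35.0
A,2000,5,12.0,30.0,35.0
A,2000,6,12.0,30.0,35.0
A,2000,7,12.0,30.0,35.0
A,2000,8,12.0,30.0,35.0
A,2000,9,12.0,30.0,35.0
A,2000,10,12.0,30.0,35.0
A,2000,11,12.0,30.0,35.0
A,2000,12,12.0,30.0,35.0
A,2001,1,12.0,30.0,35.0
A,2001,2,12.0,30.0,35.0
A,2001,3,12.0,30.0,35.0
A,2001,4,12.0,30.0,35.0
A,2001,5,12.0,30.0,35.0
A,2001,6,12.0,30.0,35.0
A,2001,7,12.0,30.0,35.0
A,2001,8,12.0,30.0,35.0
A,2001,9,12.0,30.0,35.0
A,2001,10,12.0,30.0,35.0
A,2001,11,12.0,30.0,35.0
A,2001,12,12.0,30.0,35.0
A,2002,1,12.0,30.0,35.0
A,2002,2,12.0,30.0,35.0
A,2002,3,12.0,30.0,35.0
A,2002,4,12.0,30.0,35.0
A,2002,5,12.0,30.0,35.0
A,2002,6,12.0,30.0,35.0
A,2002,7,12.0,30.0,35.0
A,2002,8,12.0,30.0,35.0
A,2002,9,12.0,30.0,35.0
A,2002,10,12.0,30.0,35.0
A,2002,11,12.0,30.0,35.0
A,2002,12,12.0,30.0,35.0
A,2003,1,12.0,30.0,35.0
A,2003,2,12.0,30.0,35.0
A,2003,3,12.0,30.0,35.0
A,2003,4,12.0,30.0,35.0
A,2003,5,12.0,30.0,35.0
A,2003,6,12.0,30.0,35.0
A,2003,7,12.0,30.0,35.0
A,2003,8,12.0,30.0,35.0
A,2003,9,12.0,30.0,35.0
A,2003,10,12.0,30.0,35.0
A,2003,11,12.0,30.0,35.0
A,2003,12,12.0,30.0,35.0
A,2004,1,12.0,30.0,35.0
A,2004,2,12.0,30.0,35.0
A,2004,3,12.0,30.0,35.0
A,2004,4,12.0,30.0,35.0
A,2004,5,12.0,30.0,35.0
A,2004,6,12.0,30.0,35.0
A,2004,7,12.0,30.0,35.0
A,2004,8,12.0,30.0,35.0
A,2004,9,12.0,30.0,35.0
A,2004,10,12.0,30.0,35.0
A,2004,11,12.0,30.0,35.0
A,2004,12,12.0,30.0,35.0
A,2005,1,12.0,30.0,35.0
A,2005,2,12.0,30.0,35.0
A,2005,3,12.0,30.0,35.0
A,2005,4,12.0,30.0,35.0
A,2005,5,12.0,30.0,35.0
A,2005,6,12.0,30.0,35.0
A,2005,7,12.0,30.0,35.0
A,2005,8,12.0,30.0,35.0
A,2005,9,12.0,30.0,35.0
A,2005,10,12.0,30.0,35.0
A,2005,11,12.0,30.0,35.0
A,2005,12,12.0,30.0,35.0
B,2000,1,12.0,60.0,38.0
B,2000,2,12.0,60.0,38.0
B,2000,3,12.0,60.0,38.0
B,2000,4,12.0,60.0,38.0
B,2000,5,12.0,60.0,38.0
B,2000,6,12.0,60.0,38.0
B,2000,7,12.0,60.0,38.0
B,2000,8,12.0,60.0,38.0
B,2000,9,12.0,60.0,38.0
B,2000,10,12.0,60.0,38.0
B,2000,11,12.0,60.0,38.0
B,2000,12,12.0,60.0,38.0
B,2001,1,12.0,60.0,38.0
B,2001,2,12.0,60.0,38.0
B,2001,3,12.0,60.0,38.0
B,2001,4,12.0,60.0,38.0
B,2001,5,12.0,60.0,38.0
B,2001,6,12.0,60.0,38.0
B,2001,7,12.0,60.0,38.0
B,2001,8,12.0,60.0,38.0
B,2001,9,12.0,60.0,38.0
B,2001,10,12.0,60.0,38.0
B,2001,11,12.0,60.0,38.0
B,2001,12,12.0,60.0,38.0
B,2002,1,12.0,60.0,38.0
B,2002,2,12.0,60.0,38.0
B,2002,3,12.0,60.0,38.0
B,2002,4,12.0,60.0,38.0
B,2002,5,12.0,60.0,38.0
B,2002,6,12.0,60.0,38.0
B,2002,7,12.0,60.0,38.0
B,2002,8,12.0,60.0,38.0
B,2002,9,12.0,60.0,38.0
B,2002,10,12.0,60.0,38.0
B,2002,11,12.0,60.0,38.0
B,2002,12,12.0,60.0,38.0
B,2003,1,12.0,60.0,38.0
B,2003,2,12.0,60.0,38.0
B,2003,3,12.0,60.0,38.0
B,2003,4,12.0,60.0,38.0
B,2003,5,12.0,60.0,38.0
B,2003,6,12.0,60.0,38.0
B,2003,7,12.0,60.0,38.0
B,2003,8,12.0,60.0,38.0
B,2003,9,12.0,60.0,38.0
B,2003,10,12.0,60.0,38.0
B,2003,11,12.0,60.0,38.0
B,2003,12,12.0,60.0,38.0
B,2004,1,12.0,60.0,38.0
B,2004,2,12.0,60.0,38.0
B,2004,3,12.0,60.0,38.0
B,2004,4,12.0,60.0,38.0
B,2004,5,12.0,60.0,38.0
B,2004,6,12.0,60.0,38.0
B,2004,7,12.0,60.0,38.0
B,2004,8,12.0,60.0,38.0
B,2004,9,12.0,60.0,38.0
B,2004,10,12.0,60.0,38.0
B,2004,11,12.0,60.0,38.0
B,2004,12,12.0,60.0,38.0
B,2005,1,12.0,60.0,38.0
B,2005,2,12.0,60.0,38.0
B,2005,3,12.0,60.0,38.0
B,2005,4,12.0,60.0,38.0
B,2005,5,12.0,60.0,38.0
B,2005,6,12.0,60.0,38.0
B,2005,7,12.0,60.0,38.0
B,2005,8,12.0,60.0,38.0
B,2005,9,12.0,60.0,38.0
B,2005,10,12.0,60.0,38.0
B,2005,11,12.0,60.0,38.0
B,2005,12,12.0,60.0,38.0
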