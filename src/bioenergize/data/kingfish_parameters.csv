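symbol,mean,sd,units,source,notes
A,0.685,0.0175,,literature,net assimilated fraction of consumed energy (losses to egestion/excretion/digestion removed)
Act_day,1.582,0.1397,m s-2,derived,mean hourly transmitted activity during the day period (0700-1800 h)
Act_night,0.808,0.0647,m s-2,derived,mean hourly transmitted activity during the night period (1900-0600 h)
Ac,0.3478,0.0782,,literature,aspect-ratio coefficient of the routine swim-speed regression
AM,2,0,,literature,activity multiplier scaling standard to active metabolic rate
AR,1.756,0.26,,measured,caudal-fin aspect ratio (n=5 photographs)
b,1.0907,0.1901,,derived,slope of the exponential metabolic rate vs activity relationship
Fj,6210,220,J g-1,literature,energy density of somatic tissue (multi-species mean)
Gv,2.158,0.2158,g day-1,assumed_10pct,daily somatic growth rate (von Bertalanffy growth converted to mass)
h_d,12,0,h,measured,hours in the day period (0700-1800 h)
h_n,12,0,h,measured,hours in the night period (1900-0600 h)
Int,-0.828,0.2299,,literature,intercept of the routine swim-speed regression (log10 km h-1)
Lc,0.6196,0.0562,,literature,length coefficient of the routine swim-speed regression
Oxy,14.14,0.135,J mgO2-1,literature,oxycalorific coefficient
Q10,1.5536,0.15536,,assumed_10pct,factor increase in standard metabolism per 10 degC
log_r,4.6423,0.1867,,derived,log-scale intercept of metabolic rate vs swimming speed
R_a,0.0067,0.00067,,assumed_10pct,intercept of the allometric mass-specific standard metabolic rate (gO2 g-1 day-1)
R_b,-0.21,0.11,,literature,mass exponent of the allometric standard metabolic rate
log_s,4.2387,0.1777,,derived,log-scale intercept of metabolic rate vs activity
SL,49,5.745,cm,measured,standard length of the study fish
Speed,0.7245,0.2376,m s-1,derived,routine swimming speed (reference value only; the morphometric model derives speed per draw)
T,23.8,0.53,degC,measured,mean field temperature within the calibrated window
W,1816.3,621.3,g,measured,wet mass of the study fish
z,1.3098,0.3843,,derived,slope of the exponential metabolic rate vs swimming speed relationship
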