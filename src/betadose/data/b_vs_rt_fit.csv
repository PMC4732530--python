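# Fitted intercept b of the one-year dose surface vs the Te-129m/Cs-137
# ratio r_t, mSv per 1000 kBq/m2 of Cs-137 deposition.
# Provenance note: the r_t=50 row is reconstructed as 1601.6; the source
# table prints "601.6", which is inconsistent with its own linear fit
# b(r_t) = 31.032 r_t + 50.009 (predicting 1601.6) and with the other
# rows, i.e. a dropped leading digit.  Downstream re-fits that must match
# the published coefficients use only the four rows r_t in {0.1, 0.5, 1, 5}.
r_t,b
0.1,53.064
0.5,65.478
1,81.1425
5,205.1310
10,360.350
50,1601.6
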