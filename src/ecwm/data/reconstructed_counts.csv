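# Reconstructed aggregate answer frequencies of a published two-arm survey
# comparing the extended crosswise model against direct questioning
# (N = 1361 university students; sensitive attribute: campus islamophobia).
# count_a counts "exactly one statement" answers (crosswise) / "agree" (direct).
# The integer counts are recovered uniquely from the printed prevalence
# estimates via ecwm.designs.reconstruct_count and cross-check against the
# printed standard errors and test statistics:
#   21.89% (SE 3.16%) at p = .158, n = 455  ->  140
#   20.50% (SE 3.13%) at p = .842, n = 456  ->  320
#   10.89% (SE 1.47%) direct,      n = 450  ->   49
group_id,design,p,n_total,count_a
ecwm_p1,crosswise,0.158,455,140
ecwm_p2,crosswise,0.842,456,320
dq,direct,,450,49
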