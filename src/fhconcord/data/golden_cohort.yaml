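# Golden synthetic-cohort preset: the designed study composition.
# 1750 participants; 866 with family history (73 increased-risk, 793
# average); 884 without. 44 actionable carriers split 10/17/17 across
# increased / average / FH-not-available (5/3/4 in secondary-findings
# genes). Increased-risk histories come from the fixed 73-family template
# mix. The seed fully determines the output.
mode: designed_counts
n_participants: 1750
n_fh_available: 866
n_increased: 73
carriers_increased: 10
carriers_average: 17
carriers_unavailable: 17
sf_carriers: [5, 3, 4]
decoy_pool_size: 1000
decoy_rate: 2.2
seed: 20210107
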