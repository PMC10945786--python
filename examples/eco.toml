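# Ecological (evolution-frozen) run at evolved trait values:
# 25 groups of 24 with 6 subgroups, 2,000 recorded days.
[population]
population_size = 600
group_size = 24
n_subgroups = 6
days = 2000
burn_in = 500
seed = 1

[traits.frozen]
alpha = 1.2
beta = 7.9
dy_new = 2.0
h_a = 0.49
h_s = 4.5
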