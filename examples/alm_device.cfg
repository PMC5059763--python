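# Alamethicin device: -200 mV / 0 mV / +100 mV steps, 10 min each.
# ALM channels are voltage-gated: open for |V| >= 60 mV, closed at 0 mV.
condition = slb_alm
protocol.sample_dt_s = 1.0

fit.P_lower_per_s = 1e-4
fit.P_upper_per_s = 10

noise.sigma_mA_cm2 = 0.0
noise.seed = 1
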