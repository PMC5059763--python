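# Gramicidin-A device: -200 mV (10 min) then 0 mV (10 min) chronoamperometry.
# The condition preset supplies pH 7 bulk, 5 mol/m3 phosphate buffer,
# P_base = 0.006, P_channel = 0.58 (always open), i0 = 10 A/m2, alpha = 0.5,
# V0 = 0 V, D_IL = 0.5 nm.
condition = slb_gA
protocol.sample_dt_s = 1.0

# permeability fit settings (used by the `fit` command)
fit.P_lower_per_s = 1e-4
fit.P_upper_per_s = 10
fit.tol = 1e-6

noise.sigma_mA_cm2 = 0.0
noise.seed = 1
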