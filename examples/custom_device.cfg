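# Fully explicit device configuration (no condition preset).
# A bare bilayer with a hypothetical half-blocked gA population, shorter
# protocol, and the nominal printed Pd/Ag-AgCl offset.
solution.pH_B = 7.0
solution.buffer.species = 5.0@7.21
solution.buffer.include_water = true

membrane.P_base_per_s = 0.006
membrane.P_channel_per_s = 0.58
membrane.block_factor = 0.5
membrane.gating.mode = always_open

electrode.i0_A_m2 = 10.0
electrode.alpha = 0.5
electrode.V0_V = 0.0
electrode.pd_thickness_nm = 50
electrode.x_max = 0.6

geometry.D_IL_nm = 0.5
geometry.contact_area_um2 = 100

protocol.voltages_V = -0.2, 0.0
protocol.durations_s = 60, 60
protocol.sample_dt_s = 0.5

initial.pH_IL = 7.0
initial.Q_H_mol_m2 = 0.0
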