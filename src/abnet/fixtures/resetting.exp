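# EpiSC resetting constraints (six experiments + Sall4 comparative),
# reconstructed from the published Methods descriptions.
experiment control_all_off_2iLIF
  bound 20
  inputs CH=on LIF=on PD=on
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=low Nanog=low Oct4=low Sall4=low Sox2=low Stat3=low Tbx3=low Tcf3=low Tfcp2l1=low
  expect never step 0..end state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high

experiment EpiSC_2iLIF
  bound 20
  inputs CH=on LIF=on PD=on
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=high Nanog=low Oct4=high Sall4=high Sox2=high Stat3=low Tbx3=low Tcf3=high Tfcp2l1=low
  expect stable state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high

experiment EpiSC_2i_only
  bound 20
  inputs CH=on LIF=off PD=on
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=high Nanog=low Oct4=high Sall4=high Sox2=high Stat3=low Tbx3=low Tcf3=high Tfcp2l1=low
  expect never step 0..end state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high

experiment EpiSC_2i_Tfcp2l1_forced
  bound 20
  inputs CH=on LIF=off PD=on
  force Tfcp2l1 high
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=high Nanog=low Oct4=high Sall4=high Sox2=high Stat3=low Tbx3=low Tcf3=high Tfcp2l1=low
  expect sustained state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Sox2=high Tbx3=high Tfcp2l1=high

experiment NanogKO_EpiSC_2iLIF
  bound 20
  inputs CH=on LIF=on PD=on
  force Nanog low
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=high Nanog=low Oct4=high Sall4=high Sox2=high Stat3=low Tbx3=low Tcf3=high Tfcp2l1=low
  expect never step 0..end state Esrrb=high Gbx2=high Klf2=high Klf4=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high

experiment NanogKO_EpiSC_LIFCH
  bound 20
  inputs CH=on LIF=on PD=off
  force Nanog low
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=high Nanog=low Oct4=high Sall4=high Sox2=high Stat3=low Tbx3=low Tcf3=high Tfcp2l1=low
  expect reached step 0..end state Esrrb=high Klf2=high Klf4=high Oct4=high Stat3=high Tfcp2l1=high

experiment Sall4_forced_2iLIF
  bound 20
  inputs CH=on LIF=on PD=on
  force Sall4 high
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=high Nanog=low Oct4=high Sall4=high Sox2=high Stat3=low Tbx3=low Tcf3=high Tfcp2l1=low

experiment Sall4_control_2iLIF
  bound 20
  inputs CH=on LIF=on PD=on
  initial Esrrb=low Gbx2=low Klf2=low Klf4=low MEKERK=high Nanog=low Oct4=high Sall4=high Sox2=high Stat3=low Tbx3=low Tcf3=high Tfcp2l1=low

comparative Sall4_no_faster treated=Sall4_forced_2iLIF reference=Sall4_control_2iLIF state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high
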