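# Maintenance-era constraints -- synthetic reconstruction of the prior
# maintenance study's behaviour shapes (self-renewal in 2i+LIF, collapse
# on withdrawal, Oct4/Sox2 essentiality); not the published model file.
experiment ESC_2iLIF_maintained
  bound 20
  inputs CH=on LIF=on PD=on
  initial Esrrb=high Gbx2=high Klf2=high Klf4=high MEKERK=low Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tcf3=low Tfcp2l1=high
  expect stable state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high

experiment ESC_withdrawal_collapse
  bound 20
  inputs CH=off LIF=off PD=off
  initial Esrrb=high Gbx2=high Klf2=high Klf4=high MEKERK=low Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tcf3=low Tfcp2l1=high
  expect never step 12..20 state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high

experiment ESC_Oct4KO_collapse
  bound 20
  inputs CH=on LIF=on PD=on
  force Oct4 low
  initial Esrrb=high Gbx2=high Klf2=high Klf4=high MEKERK=low Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tcf3=low Tfcp2l1=high
  expect never step 12..20 state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Sall4=high Sox2=high Stat3=high Tbx3=high Tfcp2l1=high

experiment ESC_Sox2KO_collapse
  bound 20
  inputs CH=on LIF=on PD=on
  force Sox2 low
  initial Esrrb=high Gbx2=high Klf2=high Klf4=high MEKERK=low Nanog=high Oct4=high Sall4=high Sox2=high Stat3=high Tbx3=high Tcf3=low Tfcp2l1=high
  expect never step 12..20 state Esrrb=high Gbx2=high Klf2=high Klf4=high Nanog=high Oct4=high Sall4=high Stat3=high Tbx3=high Tfcp2l1=high
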