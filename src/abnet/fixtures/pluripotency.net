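# Naive-pluripotency resetting ABN -- synthetic reconstruction from the
# published roster and interaction descriptions (not the original
# supplementary model file).
component LIF signal
component CH signal
component PD signal
component Oct4 gene conditions=0-8
component Sox2 gene conditions=0-8
component Nanog gene conditions=0-8
component Esrrb gene conditions=0-8
component Klf2 gene conditions=0-8
component Klf4 gene conditions=0-8
component Tbx3 gene conditions=0-8
component Tfcp2l1 gene conditions=0-8
component Gbx2 gene conditions=0-8
component Sall4 gene conditions=0-8
component Stat3 gene conditions=0-8
component MEKERK gene conditions=0-8
component Tcf3 gene conditions=0-8
LIF -> Stat3 definite
CH -| Tcf3 definite
PD -| MEKERK definite
Tcf3 -> Tcf3 definite
MEKERK -> MEKERK definite
Stat3 -> Tfcp2l1 definite
Stat3 -> Klf4 definite
Stat3 -> Gbx2 definite
Esrrb -> Tfcp2l1 definite
Tcf3 -| Tfcp2l1 definite
Sall4 -> Esrrb definite
Nanog -> Esrrb definite
Tfcp2l1 -> Esrrb definite
Tcf3 -| Esrrb definite
MEKERK -| Nanog definite
Oct4 -> Sox2 optional
Sox2 -> Oct4 optional
Oct4 -> Sall4 optional
Sall4 -> Oct4 optional
Sox2 -> Sall4 optional
Sall4 -> Sox2 optional
Oct4 -> Nanog optional
Nanog -> Oct4 optional
Sox2 -> Nanog optional
Nanog -> Sox2 optional
Esrrb -> Oct4 optional
Esrrb -> Sox2 optional
Esrrb -> Sall4 optional
MEKERK -| Esrrb optional
Tbx3 -> Tfcp2l1 optional
Gbx2 -> Tfcp2l1 optional
Klf2 -> Tfcp2l1 optional
Klf4 -> Tfcp2l1 optional
Tfcp2l1 -> Nanog optional
Klf2 -> Nanog optional
Oct4 -> Klf2 optional
MEKERK -| Klf2 optional
Klf2 -> Klf4 optional
Esrrb -> Klf4 optional
Nanog -> Klf4 optional
Esrrb -> Tbx3 optional
Klf4 -> Tbx3 optional
Tfcp2l1 -> Tbx3 optional
MEKERK -| Tbx3 optional
Klf2 -> Gbx2 optional
Tfcp2l1 -> Stat3 optional
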