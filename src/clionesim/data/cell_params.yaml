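# Maximal conductances (uS) of the eight membrane currents, one block per
# cell class.  Column identities, in the canonical order used everywhere in
# the package:
#   g_K      potassium leak
#   g_Na     sodium leak
#   g_NaV    slow voltage-dependent Na
#   g_B      slow chemosensitive B-current
#   g_NaTTX  fast TTX-sensitive Na (spike upstroke)
#   g_KTEA   TEA-sensitive delayed rectifier (spike downstroke)
#   g_Ca     voltage-gated Ca
#   g_CaCa   Ca-activated Ca current
# The SRC set yields irregular spiking-bursting; the other three sets yield
# irregular spiking.
version: 1
cell_classes:
  hunting:
    g_K: 0.25
    g_Na: 0.0231
    g_NaV: 0.11
    g_B: 0.1372
    g_NaTTX: 400.0
    g_KTEA: 10.0
    g_Ca: 1.5
    g_CaCa: 0.02
  SRC:
    g_K: 0.25
    g_Na: 0.02
    g_NaV: 0.11
    g_B: 0.128
    g_NaTTX: 400.0
    g_KTEA: 10.0
    g_Ca: 1.0
    g_CaCa: 0.01
  cerebral:
    g_K: 0.25
    g_Na: 0.0231
    g_NaV: 0.0795
    g_B: 0.1372
    g_NaTTX: 400.0
    g_KTEA: 10.0
    g_Ca: 1.5
    g_CaCa: 0.02
  CPG:
    g_K: 0.25
    g_Na: 0.0231
    g_NaV: 0.0807
    g_B: 0.1372
    g_NaTTX: 400.0
    g_KTEA: 10.0
    g_Ca: 2.0
    g_CaCa: 0.02
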