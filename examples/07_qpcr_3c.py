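"""ChIP-qPCR percent input and 3C relative interaction frequency.

Percent input converts IP and dilution-adjusted input Ct values into the
fraction of chromatin recovered; 3C frequencies are expressed relative to a
neutral control locus.
"""

import pandas as pd

from epilink import percent_input, relative_interaction_frequency

qpcr = pd.DataFrame({
    "site": ["enhancer_E1", "enhancer_E1_stim", "negative_ctrl"],
    "ct_ip": [26.64, 23.64, 28.96],
    "ct_input": [20.0, 20.0, 20.0],
    "input_fraction": [0.01, 0.01, 0.01],
})
print(percent_input(qpcr)[["site", "percent_input"]].round(3))
print("percent input = 100 * 2^((Ct_input - log2(1/fraction)) - Ct_IP)")

threec = {"RASSF6_like": 5.0, "CXCL1_prom": 15.0, "CXCL8_prom": 11.0, "intronic": 4.5}
rif = relative_interaction_frequency(threec, "RASSF6_like")
print(rif.round(2))
print("ratios > 1: locus contacts the viewpoint more often than the neutral control.")
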