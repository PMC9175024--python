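"""Elimination-route accounting: where does an Rh2 dose end up?

Closed-form branching-ratio percentages are cross-checked against
brute-force ODE flux integration.  Percentages are of the administered
dose; 'total PPD' is the fraction entering the systemic circulation in
PPD form.
"""

import deglypk as d

params = d.rat_reference_parameters()

for mode, closed in (("IV", d.iv_route_fractions(params)), ("PO", d.po_route_fractions(params))):
    oracle = d.route_fraction_oracle(params, mode)
    print(f"--- {mode} administration of Rh2 ---")
    for key, value in closed.as_dict().items():
        print(f"{key:22s} {value:6.2f}%   (flux oracle {oracle.as_dict()[key]:6.2f}%)")
print("After I.V. ~11% and after P.O. ~20% of the dose reaches plasma as PPD.")
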