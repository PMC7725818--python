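"""Fit the mean GM(1,1) to the embedded cumulative case-count series.

Prints the development coefficient a (negative: the series grows), the grey
action quantity b, the mean relative error of the plain simulation, and
whether the residual sequence has a one-signed tail that the classical
residual-GM correction could model.
"""

import greyresid as gr

fixture = gr.covid_fixture("corrected")
model = gr.fit_gm(fixture.train)
sim = gr.simulate(model, fixture.train.size)
report = gr.error_report(fixture.train, sim)
res = gr.residuals(fixture.train, sim)

print(f"development coefficient a = {model.a:.6f}  (e^-a = {2.718281828**-model.a:.4f} growth/step)")
print(f"grey action quantity   b = {model.b:.2f} cases")
print(f"fit MRE = {report.mape_percent:.4f}%  (mean |relative error| of the simulation)")
print(f"modellable residual tail: {res.k0}  (None: signs alternate, classical correction inapplicable)")
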