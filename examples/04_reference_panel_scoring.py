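"""Score samples with the packaged published PCOS diagnostic panel.

The panel combines two serum lipids, PI (18:0/20:3)-H (feature 1033NEG) and
PE (18:1p/22:6)-H (877NEG), through

    z = -19.62541206 + 2.249933588 * x(1033NEG) + 0.634268314 * x(877NEG)
    p = 1 / (1 + e^-z)

with a positive call when p exceeds the cutoff 0.83.
"""

from lipopanel import classify, panel_score, reference_panel

model = reference_panel()
print("panel members:", model.annotations)
print(f"cutoff: {model.cutoff}")

for x1, x2 in [(8.0, 2.0), (9.0, 3.0), (10.0, 4.0)]:
    x = {"1033NEG": x1, "877NEG": x2}
    p = float(panel_score(model, x))
    print(f"x(1033NEG)={x1:5.1f}  x(877NEG)={x2:4.1f}  ->  p = {p:.5f}  [{classify(model, x)}]")
print("\np is the modelled probability of PCOS; higher expression of either")
print("lipid raises it (both coefficients are positive).")
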