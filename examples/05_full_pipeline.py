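"""Run the whole analysis from one config with a single master seed.

Equivalent to `lipopanel run-all --seed 7 --out run/` but from Python; a
scaled-down simulate block keeps it quick.  The report is a plain dict and,
given the same seed, reproduces bit for bit.
"""

import json

from lipopanel import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=7,
    simulate={"n_case": 60, "n_control": 20, "n_features": 200, "n_weak": 8},
    n_permutations=50,
    validate_repeats=5,
)
report = run_pipeline(config)

print("selected panel:", report["selection"]["panel"],
      "(planted:", report["truth"]["strong"], ")")
print("OPLS-DA: R2Y %.3f, Q2 %.3f, permutation p %.4f" % (
    report["oplsda"]["r2y"], report["oplsda"]["q2"], report["oplsda"]["permutation_p_q2"]))
print("median CV metrics per validation model:")
print(json.dumps(report["validation"], indent=2))
print("held-out panel metrics:")
print(json.dumps({k: round(v, 4) for k, v in report["panel"].items()
                  if isinstance(v, float)}, indent=2))
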