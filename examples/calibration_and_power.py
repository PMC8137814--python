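"""Characterise the block-bootstrap test: type-I error and power.

A scaled-down version of the package's standard experiments: the
per-channel rate of p <= 0.01 on independent AR-noise dyads (compared with
the naive sample-wise permutation control), and detection rates on dyads
with planted coupling. Note the exceedance p-value is discrete: with B
bootstrap replicates the exchangeable null level of p <= 0.01 is
(floor(0.01 B) + 1)/(B + 1), not 0.01.
"""

from interbrain.experiments import null_calibration, power_experiment

block = null_calibration(n_dyads=15, B=200, seed=0)
iid = null_calibration(n_dyads=15, B=200, seed=0, block=1)
print(f"type-I rate at alpha=0.01 over {block.n_tests} null channel tests")
print(f"  block bootstrap (ACF-derived lags {min(block.lags)}-{max(block.lags)}): "
      f"{block.rate:.4f}")
print(f"  i.i.d. permutation control:                 {iid.rate:.4f}")
print(f"  exchangeable finite-B level:                {block.expected_level:.4f}")
print("blocks preserve serial dependence, so their null has realistic spread;")
print("sample-wise shuffling destroys it and wildly over-rejects.\n")

power = power_experiment(gains=(0.2, 0.4), n_dyads=4, B=100, seed=1)
print(power.to_string(index=False))
print("detection should rise with coupling gain and stay near the nominal "
      "level on uncoupled channels.")
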