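"""How much do the six models agree about who is high risk?

Runs the full pipeline on a synthetic cohort, then prints the Spearman
rank-concordance range, the per-model high-risk shares under both
threshold schemes, the chi-square tests of independence, and the
discordance count (participants called low risk by one model but high
risk by another).  High rank concordance alongside wildly different
high-risk shares is the package's key phenomenon: the models order people
similarly but disagree on absolute risk.
"""

import json
import tempfile
from pathlib import Path

from cvdcompare.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    run_pipeline(RunConfig(simulate_n=1345, seed=1, out=tmp))
    report = json.loads((Path(tmp) / "comparison.json").read_text())

print(f"n = {report['n']}")
print(f"Spearman rank concordance between models: "
      f"{report['spearman']['min']:.2f} to {report['spearman']['max']:.2f}")
for scheme, entry in report["schemes"].items():
    chi2 = entry["chi2_categories"]
    print(f"\n[{scheme} thresholds]  chi-square = {chi2['statistic']:.0f}, "
          f"df = {chi2['df']}, p = {chi2['p']:.2g}")
    for mid, pct in entry["high_pct"].items():
        print(f"  {mid:<18} {pct:>5.1f}% high risk")
    print(f"  discordant participants: {entry['discordant_n']}")
print("\nThe models rank participants almost identically (rho ~0.9) yet "
      "the share flagged high risk\nspans a several-fold range -> treatment "
      "decisions depend heavily on the model chosen.")
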