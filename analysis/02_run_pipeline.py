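#!/usr/bin/env python
"""Run the full association workflow on the simulated study.

Executes filtering, discovery SVA with lambda QC, threshold-scan candidate
selection, replication with Bonferroni correction, PRS construction and
replication testing, prediction-model evaluation and the subnetwork
permutation test; copies the small result tables into results/.
"""

import json
import shutil
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from netseed.pipeline import run_pipeline  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = ROOT / "scratch" / "study" / "run.yaml"
    if not config.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    out = ROOT / "scratch" / "study" / "out"
    report = run_pipeline(config, out_dir=out)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in ("run_report.json", "sva_discovery.tsv", "sva_replication.tsv",
                 "prs_association.tsv", "topology_test.json"):
        src = out / name
        if src.exists():
            shutil.copy(src, results / name)

    c, m = report.counts, report.metrics
    print(f"{c['discovery_variants_in']} variants -> "
          f"{c['discovery_variants_kept']} in the seed network +/- 20 kbp")
    print(f"discovery SVA: lambda = {m['lambda_discovery']:.3f}; "
          f"{c['candidates']} candidates at p < "
          f"{report.thresholds['candidate_p']:g}")
    print(f"replication: {c.get('replication_significant', 0)} significant "
          f"after Bonferroni "
          f"(cutoff {report.thresholds['bonferroni_replication']:.4f})")
    if "prs_or" in m:
        lo, hi = m["prs_ci"]
        print(f"PRS ({c['prs_variants']} variants): OR {m['prs_or']:.2f} "
              f"(95% CI {lo:.2f}-{hi:.2f}; p = {m['prs_p']:.2e}); "
              f"upper quartile holds "
              f"{100 * m['prs_upper_quartile_case_fraction']:.0f}% of cases vs "
              f"{100 * m['prs_upper_quartile_control_fraction']:.0f}% of controls")
    if "prediction" in m:
        for name, e in m["prediction"].items():
            print(f"{name}: balanced accuracy {e['balanced_accuracy']:.2f}, "
                  f"AUC {e['auc']:.2f} "
                  f"({e['auc_ci'][0]:.2f}-{e['auc_ci'][1]:.2f})")
    t = m.get("topology")
    if t:
        print(f"topology ({t['subset_size']} genes, LCC {t['lcc_size']}): "
              f"APL {t['apl']:.2f} (p_lower {t['p_apl_lower']:.3g}), "
              f"ACC {t['acc']:.2f} (p_upper {t['p_acc_upper']:.3g}) over "
              f"{t['n_permutations']} permutations")
    print(f"tables copied to {results}")
    print(json.dumps(report.counts, indent=2))


if __name__ == "__main__":
    main()
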