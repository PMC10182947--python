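"""Train the global toxicity model and the five one-vs-all mechanism models.

For each model: latent variables chosen by repeated stratified 3-fold CV
(lowest classification error), ROC from out-of-fold predictions, decision
threshold at the sensitivity/specificity intersection, and VIP biomarker
ranking. Writes the model summary, the VIP > 1.5 biomarker table and the
serialized model artefacts.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir, study

from mechtox import rank_biomarkers


def main():
    res = study()
    out = outdir()

    rows = []
    for mid, mm in res.trained.models.items():
        rows.append({
            "model": mid,
            "n_lv": mm.cv.n_lv,
            "cv_auc_mean": round(mm.cv.auc_mean, 3),
            "cv_auc_sd": round(mm.cv.auc_sd, 3),
            "threshold": round(mm.threshold, 3),
            "n_pos": int(sum(mm.y == 1)),
            "n_neg": int(sum(mm.y == 0)),
            "validated": mm.validated,
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "03_model_summary.tsv", sep="\t", index=False)
    # full artefacts (weights, CV scores, scalers) run to a few MB -> scratch
    scratch = out.parent / "scratch" / "analysis_data"
    scratch.mkdir(parents=True, exist_ok=True)
    res.trained.save(scratch / "models.json")

    bio = rank_biomarkers(res.trained, res.train_table, vip_cut=1.5)
    bio.to_csv(out / "03_vip_biomarkers.tsv", sep="\t", index=False)

    print(summary.to_string(index=False))
    print(f"\n{len(bio)} biomarker entries at VIP > 1.5 "
          f"({bio['feature'].nunique()} distinct features)")
    print(f"planted-marker recovery: "
          f"{100 * res.metrics['marker_vip_recovery']:.0f}%")


if __name__ == "__main__":
    main()
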