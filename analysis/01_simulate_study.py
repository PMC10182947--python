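"""Simulate the training and test studies with planted ground truth.

Training design: 5 single-mechanism hepatotoxicants per mechanism (OS, MI,
APT, ST, CHOL) plus 9 non-toxic compounds, each at IC10 and IC50 in
quadruplicate, spread over 4 batches with pooled QCs every 8 injections,
controls and blanks. Test design: 25 compounds with one planted dominant
mechanism at 1/10/100/1000 uM. Writes the design summary and the planted
signature table; the full feature tables (a few MB) land under scratch/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SEED, outdir, study

from mechtox import write_feature_table, write_pathway_db
from mechtox.synth import write_ground_truth


def main():
    res = study()
    out = outdir()
    scratch = out.parent / "scratch" / "analysis_data"
    scratch.mkdir(parents=True, exist_ok=True)

    sig_rows = []
    for s in res.signatures:
        for f, d in zip(s.marker_features, s.directions):
            sig_rows.append({"mechanism": s.mechanism, "feature": f,
                             "direction": d, "effect_size": s.effect_size})
    sigs = pd.DataFrame(sig_rows)
    sigs.to_csv(out / "01_planted_signatures.tsv", sep="\t", index=False)

    counts = res.train_table.samples["type"].value_counts()
    print(f"training study (seed {SEED}): {res.train_table.n_samples} samples "
          f"x {res.train_table.n_features} annotated features after filters")
    print(counts.to_string())
    print(f"planted markers: {len(sigs)} across "
          f"{sigs['mechanism'].nunique()} mechanisms")

    write_feature_table(res.train_table, scratch / "train")
    write_feature_table(res.test_table, scratch / "test")
    write_pathway_db(res.pathway_db, scratch / "pathways.gmt",
                     scratch / "pathways.edges.tsv")
    write_ground_truth(res.signatures, res.train_table,
                       scratch / "train_ground_truth.json")
    print(f"feature tables and pathway DB written under {scratch}")


if __name__ == "__main__":
    main()
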