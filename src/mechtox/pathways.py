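"""Pathway analysis per mechanism: metabolite t-tests, over-representation,
topology impact, and the (p, impact) fingerprint.

For each mechanism the annotated metabolites are tested (Welch two-sample
t-test) against control samples; pathway significance is the hypergeometric
tail of the significant "hits" among the measured, annotated background; the
impact factor is the sum of the normalized relative-betweenness-centrality
importances of the hit metabolites within the pathway graph. Pathways enter
the analysis only when they have more than three measured hits... strictly:
pathways are retained in the fingerprint when n_hits > 3; the reportable
subset additionally satisfies p < 0.05 and impact > 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, Pathway, PathwayDB, ValidationError


@dataclass
class MetaboliteTest:
    feature: str
    key: str  # annotation key used for pathway matching
    t: float
    p_value: float
    direction: int  # sign of the mechanism-vs-control mean difference


@dataclass
class PathwayFingerprint:
    """Per-mechanism MetPA outcome: one (n_hits, p, -log10 p, impact) row per
    retained pathway (n_hits > 3); ``reportable`` flags p < 0.05 & impact > 0.01."""

    mechanism: str
    entries: pd.DataFrame  # index pathway id; columns n_hits, p_value, neg_log10_p, impact, reportable, name

    def reportable(self) -> pd.DataFrame:
        return self.entries[self.entries["reportable"]]


def metabolite_ttests(
    table: FeatureTable, mechanism_samples, control_samples
) -> list[MetaboliteTest]:
    """Welch t-test per annotated metabolite, mechanism group vs controls."""
    mech_ids = list(mechanism_samples)
    ctrl_ids = list(control_samples)
    if len(mech_ids) < 2 or len(ctrl_ids) < 2:
        raise ValidationError("each group needs >= 2 samples for a t-test")
    keys = table.annotation_keys()
    annotated = table.features.index[table.features["hmdb_id"].notna()]
    out: list[MetaboliteTest] = []
    A = table.intensities.loc[mech_ids, annotated].to_numpy(float)
    B = table.intensities.loc[ctrl_ids, annotated].to_numpy(float)
    t, p = stats.ttest_ind(A, B, axis=0, equal_var=False, nan_policy="omit")
    diff = np.nanmean(A, axis=0) - np.nanmean(B, axis=0)
    for fid, ti, pi, di in zip(annotated, t, p, diff):
        if not np.isfinite(pi):  # zero-variance degenerate feature
            ti, pi = 0.0, 1.0
        out.append(
            MetaboliteTest(fid, str(keys.loc[fid]), float(ti), float(pi),
                           int(np.sign(di)) if di != 0 else 0)
        )
    return out


def pathway_enrichment(
    tests: list[MetaboliteTest], db: PathwayDB, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation of significant metabolites.

    Background = all measured annotated metabolites that appear in the tests;
    hits = pathway members significant at ``alpha`` (unadjusted). The p-value
    is the upper hypergeometric tail P(X >= hits).
    """
    measured = {t.key for t in tests}
    if not measured:
        raise ValidationError("empty background: no annotated measured metabolites")
    significant = {t.key for t in tests if t.p_value < alpha}
    M, n_sig = len(measured), len(significant)
    rows = []
    for pw in db:
        members_measured = set(pw.members) & measured
        hits = members_measured & significant
        K = len(members_measured)
        k = len(hits)
        if K == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, n_sig, K))
        rows.append({"pathway": pw.id, "name": pw.name, "n_measured": K,
                     "n_hits": k, "p_value": min(p, 1.0)})
    return pd.DataFrame(rows).set_index("pathway")


def _importance(pw: Pathway) -> dict[str, float]:
    """Node importance: relative betweenness centrality within the pathway
    graph, normalized to sum 1; uniform when the graph is too small (< 3
    edges) or centrality-degenerate; all-zero when no graph is available
    (impact cannot be scored without topology)."""
    members = sorted(pw.members)
    uniform = {m: 1.0 / len(members) for m in members}
    if pw.graph is None:
        return {m: 0.0 for m in members}
    if pw.graph.number_of_edges() < 3:
        return uniform
    bc = nx.betweenness_centrality(pw.graph, normalized=True)
    total = sum(bc.get(m, 0.0) for m in members)
    if total <= 0:
        return uniform
    return {m: bc.get(m, 0.0) / total for m in members}


def pathway_impact(tests: list[MetaboliteTest], db: PathwayDB,
                   alpha: float = 0.05) -> pd.Series:
    """Topology impact per pathway: sum of normalized node importances of the
    significant members. In [0, 1]; 1 when every member is a hit; 0 for
    pathways without a graph and without hits alike."""
    significant = {t.key for t in tests if t.p_value < alpha}
    out = {}
    for pw in db:
        imp = _importance(pw)
        out[pw.id] = float(sum(v for m, v in imp.items() if m in significant))
    return pd.Series(out, name="impact")


def metpa(
    table: FeatureTable,
    mechanism_samples,
    control_samples,
    db: PathwayDB,
    mechanism: str = "",
    alpha: float = 0.05,
    min_hits: int = 3,
    adjust: str | None = None,
) -> PathwayFingerprint:
    """Compose t-tests, enrichment and impact into a pathway fingerprint.

    ``adjust="bh"`` applies Benjamini-Hochberg to the metabolite p-values
    before hit calling (off by default). Pathways with n_hits > ``min_hits``
    are retained; the reportable subset has p < 0.05 and impact > 0.01.
    """
    tests = metabolite_ttests(table, mechanism_samples, control_samples)
    if adjust == "bh":
        ps = np.array([t.p_value for t in tests])
        adj = _benjamini_hochberg(ps)
        tests = [
            MetaboliteTest(t.feature, t.key, t.t, float(q), t.direction)
            for t, q in zip(tests, adj)
        ]
    if all(pw.graph is None for pw in db):
        warnings.warn("pathway database has no graphs; impacts fall back to "
                      "uniform importance")
    enr = pathway_enrichment(tests, db, alpha=alpha)
    impact = pathway_impact(tests, db, alpha=alpha)
    enr["impact"] = impact
    enr["neg_log10_p"] = -np.log10(enr["p_value"].clip(lower=1e-300))
    enr = enr[enr["n_hits"] > min_hits].copy()
    enr["reportable"] = (enr["p_value"] < 0.05) & (enr["impact"] > 0.01)
    cols = ["name", "n_measured", "n_hits", "p_value", "neg_log10_p", "impact",
            "reportable"]
    return PathwayFingerprint(mechanism, enr[cols])


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
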