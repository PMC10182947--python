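"""End-to-end study runner over synthetic data with planted ground truth.

This module wires the full strategy together: simulate a training study
(mechanism-labelled hepatotoxicants at IC10/IC50, non-toxic compounds,
controls, blanks, QCs), condition the data (QC-SVR drift correction,
between-batch ratio correction, QC-RSD and blank filters), train the global
and one-vs-all mechanism discriminants, simulate and score a fixed-ladder
test study, compute per-mechanism pathway fingerprints and their pairwise
Mantel meta-analysis, and report recovery of the planted truth.

The study conditions (sample sizes, noise levels, effect sizes) are the
package defaults documented in docs/methods.md; `run_demo_study` is the
single entry point used by the analysis scripts and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MECHANISMS, FeatureTable, PathwayDB
from .mantel import pairwise_mechanism_matrix
from .mech_models import (
    RADAR_AXES,
    TrainConfig,
    TrainedModels,
    ToxicityProfile,
    assemble_training,
    concordance_summary,
    predict_profiles,
    rank_biomarkers,
    train_all,
)
from .pathways import PathwayFingerprint, metpa
from .preprocess import (
    CorrectionReport,
    between_batch_correct,
    blank_filter,
    qc_rsd,
    qcsvrc_correct_all,
    rsd_filter,
)
from .synth import (
    CompoundSpec,
    GeneratorConfig,
    SignatureSpec,
    StudyDesign,
    default_signatures,
    generate_pathway_db,
    generate_study,
)


def demo_training_design(seed: int = 0, n_per_mechanism: int = 5,
                         n_nontoxic: int = 9,
                         replicates: int = 4, n_batches: int = 4,
                         n_controls_per_batch: int = 8) -> StudyDesign:
    """Balanced training design: ``n_per_mechanism`` single-mechanism
    hepatotoxicants per modelled mechanism plus non-toxic compounds, each at
    IC10 and IC50 in quadruplicate, with untreated controls in every batch
    (the negative probes roughly match the toxic probes in number)."""
    rng = np.random.default_rng(seed)
    compounds = []
    for mech in MECHANISMS:
        for i in range(n_per_mechanism):
            ic50 = float(10 ** rng.uniform(1.0, 3.0))  # 10..1000 uM
            ratio = float(10 ** rng.uniform(0.4, 1.2))  # IC50/IC10 in ~2.5..16
            compounds.append(
                CompoundSpec(f"{mech}_cmpd{i + 1}", mech, ic10=ic50 / ratio,
                             ic50=ic50)
            )
    for i in range(n_nontoxic):
        compounds.append(
            CompoundSpec(f"NT_cmpd{i + 1}", "NT", ic10=1e5, ic50=1e6)
        )
    return StudyDesign(tuple(compounds), n_batches=n_batches,
                       replicates_per_condition=replicates,
                       n_controls_per_batch=n_controls_per_batch,
                       design_kind="train_ic")


def demo_test_design(seed: int = 1, n_compounds: int = 25,
                     secondary_fraction: float = 0.4,
                     n_nontoxic: int = 5,
                     replicates: int = 4, n_batches: int = 4) -> StudyDesign:
    """Test design: compounds with one planted dominant mechanism (optionally
    a weaker secondary one) examined at the fixed 1/10/100/1000 uM ladder."""
    rng = np.random.default_rng(seed)
    compounds = []
    for i in range(n_compounds):
        mech = MECHANISMS[i % len(MECHANISMS)]
        ic50 = float(10 ** rng.uniform(1.0, 2.5))  # potent enough that 1000 uM saturates
        ratio = float(10 ** rng.uniform(0.4, 1.2))
        secondary = None
        if rng.random() < secondary_fraction:
            others = [m for m in MECHANISMS if m != mech]
            secondary = str(rng.choice(others))
        compounds.append(
            CompoundSpec(f"T{i + 1:02d}_{mech}", mech, ic10=ic50 / ratio,
                         ic50=ic50, mechanism_secondary=secondary)
        )
    for i in range(n_nontoxic):
        compounds.append(CompoundSpec(f"Tnt{i + 1}", "NT", ic10=1e5, ic50=1e6))
    return StudyDesign(tuple(compounds), n_batches=n_batches,
                       replicates_per_condition=replicates,
                       design_kind="test_fixed")


def reference_compound_panel() -> tuple[CompoundSpec, ...]:
    """A curated panel of 29 reference compounds with literature primary and
    secondary hepatotoxicity mechanisms and IC10/IC50 values (uM) from MTT
    dose-response curves in a HepG2 model; the non-toxic entries list the
    concentration pair used in their study arm."""
    t = [
        # name, primary, secondary, ic10, ic50
        ("acetaminophen", "OS", "APT", 500, 2000),
        ("acetylsalicylic_acid", "OS", "ST", 5000, 20000),
        ("aflatoxin_b1", "OS", "APT", 100, 500),
        ("amoxicillin_clavulanate", "OS", "CHOL", 1094, 2190),
        ("azathioprine", "OS", "APT", 173, 600),
        ("chlorpromazine", "OS", "CHOL", 0.5, 60),
        ("dantrolene", "OS", None, 5, 40),
        ("erythromycin", "OS", "APT", 220, 3200),
        ("levofloxacin", "OS", "ST", 235, 5800),
        ("mercaptopurine", "OS", "APT", 25, 50),
        ("rifampicin", "OS", None, 50, 100),
        ("amiodarone", "MI", "ST", 13, 30),
        ("bosentan", "MI", "CHOL", 60, 590),
        ("carbamazepine", "MI", None, 200, 1000),
        ("clozapine", "MI", None, 22, 70),
        ("diclofenac", "MI", "APT", 320, 700),
        ("flutamide", "MI", None, 30, 600),
        ("isoniazid", "MI", None, 1000, 10000),
        ("phenytoin", "MI", None, 100, 500),
        ("stavudine", "MI", None, 500, 1000),
        ("tetracycline", "MI", "ST", 100, 2000),
        ("troglitazone", "MI", "APT", 50, 300),
        ("valproic_acid", "MI", "ST", 1000, 5000),
        ("captopril", "APT", None, 250, 500),
        ("thiabendazole", "CHOL", None, 10, 500),
        ("dmso", "NT", None, 0.5, 5),
        ("glucose", "NT", None, 5000, 50000),
        ("acetylcysteine", "NT", None, 100, 1000),
        ("thiamine", "NT", None, 100, 1000),
    ]
    return tuple(
        CompoundSpec(name, prim, ic10=float(ic10), ic50=float(ic50),
                     mechanism_secondary=sec)
        for name, prim, sec, ic10, ic50 in t
    )


@dataclass
class PreprocessResult:
    table: FeatureTable
    report: CorrectionReport
    qc_rsd_before: pd.Series
    qc_rsd_after: pd.Series


def preprocess_study(table: FeatureTable, rsd_threshold: float = 30.0,
                     blank_fold: float = 3.0,
                     apply_filters: bool = True) -> PreprocessResult:
    """Standard conditioning chain: within-batch QC-SVR correction,
    between-batch ratio correction, then (optionally) the QC-RSD and
    blank-ratio feature filters."""
    report = CorrectionReport()
    rsd_before = qc_rsd(table)
    corrected = qcsvrc_correct_all(table, report=report)
    corrected = between_batch_correct(corrected, report=None)
    rsd_after = qc_rsd(corrected)
    out = corrected
    if apply_filters:
        out, rep_rsd = rsd_filter(out, threshold_pct=rsd_threshold)
        out, rep_blank = blank_filter(out, fold=blank_fold)
        report.features_removed_rsd = rep_rsd.features_removed_rsd
        report.features_removed_missing_qc = rep_rsd.features_removed_missing_qc
        report.features_removed_blank = rep_blank.features_removed_blank
        report.qc_rsd_after = rep_rsd.qc_rsd_after
    report.qc_rsd_before = {f: float(r) for f, r in rsd_before.items()
                            if np.isfinite(r)}
    return PreprocessResult(out, report, rsd_before, rsd_after)


@dataclass
class StudyResult:
    """Everything `run_demo_study` computed, plus headline numbers."""

    metrics: dict
    trained: TrainedModels | None = None
    train_table: FeatureTable | None = None
    test_table: FeatureTable | None = None
    profiles: list[ToxicityProfile] | None = None
    fingerprints: list[PathwayFingerprint] | None = None
    pathway_db: PathwayDB | None = None
    signatures: list[SignatureSpec] | None = None
    mantel_r: pd.DataFrame | None = None
    mantel_p: pd.DataFrame | None = None
    biomarkers: pd.DataFrame | None = None
    concordance: pd.DataFrame | None = None


def _fingerprints_for_table(table: FeatureTable, db: PathwayDB,
                            mechanisms=MECHANISMS) -> list[PathwayFingerprint]:
    controls = table.samples.index[table.samples["type"] == "control"]
    fps = []
    for mech in mechanisms:
        mask = (table.samples["type"] == "treated") & (
            table.samples["mechanism_label"] == mech
        )
        fps.append(
            metpa(table, table.samples.index[mask], controls, db,
                  mechanism=mech)
        )
    return fps


def run_demo_study(
    seed: int = 0,
    n_features: int = 500,
    markers_per_mechanism: int = 12,
    n_general_markers: int = 15,
    n_per_mechanism: int = 5,
    n_test_compounds: int = 25,
    mantel_replicates: int = 3,
    train_config: TrainConfig | None = None,
    mantel_B: int = 999,
    n_pathways: int = 20,
    keep_artifacts: bool = True,
) -> StudyResult:
    """Run the full strategy on a seeded synthetic study and measure recovery
    of the planted ground truth.

    Returns a :class:`StudyResult` whose ``metrics`` dict contains, among
    others: the fraction of features with QC RSD < 30%, per-model CV AUCs,
    planted-marker recovery at VIP > 1.5, the dominant-mechanism recovery
    rate on held-out test compounds at their top concentration, the
    fraction of planted pathways that are reportable, and the number of
    significant pairwise Mantel correlations between mechanism fingerprints.
    """
    master = np.random.default_rng(seed)
    s_sig, s_design, s_gen, s_testd, s_testg, s_db = [
        int(x) for x in master.integers(0, 2**31 - 1, size=6)
    ]
    signatures = default_signatures(
        n_features=n_features, markers_per_mechanism=markers_per_mechanism,
        n_general_markers=n_general_markers, seed=s_sig,
    )
    design = demo_training_design(seed=s_design,
                                  n_per_mechanism=n_per_mechanism)
    gen_cfg = GeneratorConfig(n_features=n_features, seed=s_gen,
                              assay_seed=s_sig)
    train_raw = generate_study(design, signatures, gen_cfg)

    prep = preprocess_study(train_raw)
    frac_rsd_ok = float((prep.qc_rsd_after < 30.0).mean())
    # models are built on the annotated metabolites (mirroring a study that
    # identifies features before modelling), not on every raw LC-MS feature
    annotated_ids = [
        f for f in prep.table.feature_ids
        if pd.notna(prep.table.features.loc[f, "hmdb_id"])
    ]
    train_table = prep.table.drop_features(
        set(prep.table.feature_ids) - set(annotated_ids)
    )

    config = train_config or TrainConfig(seed=seed)
    assembly = assemble_training(train_table)
    trained = train_all(train_table, assembly, config)
    aucs = {m: trained.models[m].cv.auc_mean for m in trained.models}

    # planted-marker recovery at VIP > 1.5 in the matching mechanism model
    surviving = set(train_table.feature_ids)
    recov = []
    for sig in signatures:
        mm = trained.models[sig.mechanism]
        high = set(mm.vip.loc[mm.vip["vip"] > 1.5, "feature"])
        markers = [m for m in sig.marker_features if m in surviving]
        recov.append(np.mean([m in high for m in markers]) if markers else np.nan)
    marker_recovery = float(np.nanmean(recov))

    # held-out test study, scored per compound x concentration
    test_design = demo_test_design(seed=s_testd, n_compounds=n_test_compounds)
    test_cfg = GeneratorConfig(n_features=n_features, seed=s_testg,
                               assay_seed=s_sig)
    test_raw = generate_study(test_design, signatures, test_cfg)
    test_prep = preprocess_study(test_raw, apply_filters=False)
    profiles = predict_profiles(trained, test_prep.table)

    by_compound: dict[str, list[ToxicityProfile]] = {}
    for p in profiles:
        by_compound.setdefault(p.compound, []).append(p)
    truth = {c.name: c.mechanism_primary for c in test_design.compounds}
    hits, n_eval = 0, 0
    for comp, plist in by_compound.items():
        if truth[comp] == "NT":
            continue
        usable = [p for p in plist if not p.excluded]
        if not usable:
            continue
        top = max(usable, key=lambda p: p.concentration)
        axis_scores = {m: top.ypred[m] for m in MECHANISMS}
        n_eval += 1
        if max(axis_scores, key=axis_scores.get) == truth[comp]:
            hits += 1
    dominant_recovery = hits / n_eval if n_eval else float("nan")

    concordance = concordance_summary(profiles, truth)
    top_row = concordance.iloc[-1] if len(concordance) else None

    # pathway fingerprints on the training study + planted-pathway truth
    keys = train_raw.annotation_keys()
    marker_sets = {
        s.mechanism: [keys.loc[f] for f in s.marker_features] for s in signatures
    }
    annotated = train_raw.features.loc[
        train_raw.features["hmdb_id"].notna()
    ]["hmdb_id"].tolist()
    db = generate_pathway_db(n_pathways, (5, 12), annotated, seed=s_db,
                             marker_sets=marker_sets)
    fingerprints = _fingerprints_for_table(train_table, db)
    planted_ok = []
    for fp in fingerprints:
        pid = next(p.id for p in db if p.name == f"synthetic {fp.mechanism} pathway")
        ok = pid in fp.entries.index and bool(fp.entries.loc[pid, "reportable"])
        planted_ok.append(ok)

    r_mat, p_mat, _ = pairwise_mechanism_matrix(fingerprints, B=mantel_B,
                                                seed=seed)
    tri = np.triu_indices(len(fingerprints), k=1)
    n_pairs = len(tri[0])
    n_sig_pairs = int((p_mat.to_numpy()[tri] < 0.05).sum())

    # replicate studies for the Mantel false-positive rate (fingerprints only)
    pair_tests, pair_nonsig = 0, 0
    for rep in range(mantel_replicates):
        rep_seed = int(np.random.default_rng(seed + 7919 * (rep + 1))
                       .integers(0, 2**31 - 1))
        rep_table = generate_study(
            design, signatures, GeneratorConfig(n_features=n_features,
                                                seed=rep_seed,
                                                assay_seed=s_sig)
        )
        rep_prep = preprocess_study(rep_table)
        rep_fps = _fingerprints_for_table(rep_prep.table, db)
        _, rep_p, _ = pairwise_mechanism_matrix(rep_fps, B=mantel_B,
                                                seed=rep_seed)
        vals = rep_p.to_numpy()[tri]
        pair_tests += len(vals)
        pair_nonsig += int((vals >= 0.05).sum())

    metrics = {
        "n_features_after_filters": train_table.n_features,
        "qc_rsd_below_30_fraction": frac_rsd_ok,
        "cv_auc": aucs,
        "min_mechanism_cv_auc": float(min(aucs[m] for m in MECHANISMS)),
        "tox_cv_auc": float(aucs["TOX"]),
        "thresholds": {m: float(trained.models[m].threshold)
                       for m in trained.models},
        "chosen_lv": {m: int(trained.models[m].cv.n_lv)
                      for m in trained.models},
        "marker_vip_recovery": marker_recovery,
        "dominant_mechanism_recovery": float(dominant_recovery),
        "n_test_compounds_evaluated": n_eval,
        "tox_positive_pct_at_top_conc": (
            float(top_row["tox_positive_pct"]) if top_row is not None else float("nan")
        ),
        "mechanism_concordance_pct_at_top_conc": (
            float(top_row["mechanism_concordance_pct"])
            if top_row is not None else float("nan")
        ),
        "planted_pathway_reportable_fraction": float(np.mean(planted_ok)),
        "mantel_significant_pairs": n_sig_pairs,
        "mantel_n_pairs": n_pairs,
        "mantel_replicate_nonsignificant_fraction": (
            pair_nonsig / pair_tests if pair_tests else float("nan")
        ),
        "mantel_max_abs_r": float(np.abs(r_mat.to_numpy()[tri]).max()),
    }
    result = StudyResult(metrics=metrics)
    if keep_artifacts:
        result.trained = trained
        result.train_table = train_table
        result.test_table = test_prep.table
        result.profiles = profiles
        result.fingerprints = fingerprints
        result.pathway_db = db
        result.signatures = list(signatures)
        result.mantel_r = r_mat
        result.mantel_p = p_mat
        result.concordance = concordance
        result.biomarkers = rank_biomarkers(trained, train_table)
    return result
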