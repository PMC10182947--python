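"""Assembly and application of the discriminant models.

Six two-class PLS-DA models are built from the training study: a global
toxicity model (TOX: toxic-compound samples at both toxic concentrations vs
non-toxic-compound samples and untreated controls) and one one-vs-all model
per mechanism (positives: samples of compounds with that primary mechanism;
negatives: everything else usable). The CHOL model is constructed like the
others but is marked non-validated — a HepG2-like system has very limited
bile-acid handling — and is excluded from the radar axes by default.

Applied to a test study, each model's continuous y-predicted value, clipped
to [0, 1], is the toxicity index of that axis; replicate wells are averaged
before thresholding, and low-protein samples are excluded with reason "LP".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MECHANISMS, FeatureTable, ValidationError, write_json
from .preprocess import Autoscaler, exclude_low_protein
from .plsda import (
    CVResult,
    PermutationResult,
    PLSFit,
    ROCResult,
    cross_validate,
    fit_pls,
    permutation_test,
    roc_from_cv,
    select_threshold,
    vip,
)

MODEL_IDS = ("TOX",) + MECHANISMS
RADAR_AXES = ("TOX", "OS", "MI", "APT", "ST")  # CHOL non-validated by default


@dataclass
class TrainingAssembly:
    """Positive/negative sample-id sets per model (a partition of the usable
    samples for every model)."""

    positives: dict[str, list[str]]
    negatives: dict[str, list[str]]

    def counts(self) -> pd.DataFrame:
        rows = {
            m: {"positive_probes": len(self.positives[m]),
                "negative_probes": len(self.negatives[m])}
            for m in self.positives
        }
        return pd.DataFrame(rows).T

    def labels(self, model_id: str) -> tuple[list[str], np.ndarray]:
        ids = self.positives[model_id] + self.negatives[model_id]
        y = np.concatenate(
            [np.ones(len(self.positives[model_id])),
             np.zeros(len(self.negatives[model_id]))]
        )
        return ids, y


def assemble_training(
    table: FeatureTable,
    dual_label: bool = False,
    mechanisms: tuple[str, ...] = MECHANISMS,
) -> TrainingAssembly:
    """Build the per-model class assignments from sample metadata.

    TOX: positives are all toxic-compound samples (both concentrations);
    negatives are non-toxic-compound samples plus untreated controls.
    Mechanism M: positives are samples of compounds whose primary mechanism
    is M; negatives are all other usable samples (other toxic compounds,
    non-toxic compounds, controls). ``dual_label`` additionally counts a
    compound's secondary mechanism as positive membership.
    """
    s = table.samples
    usable = s[s["type"].isin(["control", "treated"])]
    treated = usable[usable["type"] == "treated"]
    missing = treated.index[treated["mechanism_label"].isna()].tolist()
    if missing:
        raise ValidationError(f"treated sample(s) without mechanism label: {missing}")

    toxic = treated[treated["mechanism_label"].isin(mechanisms)]
    nontoxic = treated[treated["mechanism_label"] == "NT"]
    controls = usable[usable["type"] == "control"]

    positives = {"TOX": list(toxic.index)}
    negatives = {"TOX": list(nontoxic.index) + list(controls.index)}

    sec = s.get("mechanism_secondary")
    for m in mechanisms:
        pos_mask = toxic["mechanism_label"] == m
        if dual_label and sec is not None:
            pos_mask = pos_mask | (sec.reindex(toxic.index) == m)
        pos = list(toxic.index[pos_mask])
        if not pos:
            raise ValidationError(f"no positive probes for mechanism {m}")
        pos_set = set(pos)
        neg = [i for i in usable.index if i not in pos_set]
        positives[m] = pos
        negatives[m] = neg
    return TrainingAssembly(positives, negatives)


@dataclass
class TrainConfig:
    max_lv: int = 8
    k: int = 3
    repeats: int = 10
    permutation_B: int = 0  # 0 disables; the full study protocol uses 200
    permutation_repeats: int = 1
    seed: int = 0
    missing: str = "error"  # or "impute_median"


@dataclass
class MechanismModel:
    """One fitted discriminant with its diagnostics and decision threshold."""

    model_id: str
    fit: PLSFit
    cv: CVResult
    roc: ROCResult
    threshold: float
    vip: pd.DataFrame
    sample_ids: list[str]
    y: np.ndarray
    permutation: PermutationResult | None = None
    validated: bool = True

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "fit": self.fit.to_dict(),
            "cv": self.cv.to_dict(),
            "roc": self.roc.to_dict(),
            "threshold": float(self.threshold),
            "vip": {"feature": self.vip["feature"].tolist(),
                    "vip": self.vip["vip"].tolist(),
                    "rank": self.vip["rank"].tolist()},
            "sample_ids": list(self.sample_ids),
            "y": self.y.tolist(),
            "permutation": self.permutation.to_dict() if self.permutation else None,
            "validated": bool(self.validated),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MechanismModel":
        return cls(
            model_id=d["model_id"],
            fit=PLSFit.from_dict(d["fit"]),
            cv=CVResult.from_dict(d["cv"]),
            roc=ROCResult.from_dict(d["roc"]),
            threshold=float(d["threshold"]),
            vip=pd.DataFrame(d["vip"]),
            sample_ids=list(d["sample_ids"]),
            y=np.asarray(d["y"], float),
            permutation=(PermutationResult.from_dict(d["permutation"])
                         if d.get("permutation") else None),
            validated=bool(d.get("validated", True)),
        )


@dataclass
class TrainedModels:
    """The six models plus the shared training autoscaler."""

    models: dict[str, MechanismModel]
    scaler: Autoscaler
    config: TrainConfig

    def save(self, path) -> None:
        payload = {
            "models": {m: mm.to_dict() for m, mm in self.models.items()},
            "scaler": self.scaler.to_dict(),
            "config": self.config.__dict__,
        }
        write_json(payload, path)

    @classmethod
    def load(cls, path) -> "TrainedModels":
        d = json.loads(Path(path).read_text())
        return cls(
            models={m: MechanismModel.from_dict(v) for m, v in d["models"].items()},
            scaler=Autoscaler.from_dict(d["scaler"]),
            config=TrainConfig(**d["config"]),
        )


def train_all(
    table: FeatureTable,
    assembly: TrainingAssembly | None = None,
    config: TrainConfig | None = None,
    mechanisms: tuple[str, ...] = MECHANISMS,
    dual_label: bool = False,
) -> TrainedModels:
    """Train the global and per-mechanism discriminants on a preprocessed
    training table.

    Latent variables are chosen per model by repeated stratified 3-fold CV;
    the ROC is built from the out-of-fold scores; the decision threshold sits
    at the sensitivity/specificity intersection; VIPs come from the final fit
    on all usable samples; an optional AUROC permutation test (B from the
    config) assesses significance.
    """
    config = config or TrainConfig()
    if assembly is None:
        assembly = assemble_training(table, dual_label=dual_label,
                                     mechanisms=mechanisms)
    usable = sorted({i for ids in assembly.positives.values() for i in ids}
                    | {i for ids in assembly.negatives.values() for i in ids})
    X_all = table.intensities.loc[usable]
    if X_all.isna().any().any():
        if config.missing == "impute_median":
            X_all = X_all.fillna(X_all.median(axis=0))
        else:
            bad = X_all.columns[X_all.isna().any()][:5].tolist()
            raise ValidationError(
                f"missing intensities (e.g. {bad}); set missing='impute_median'"
            )
    scaler = Autoscaler().fit(X_all)
    Z_all = scaler.transform(X_all)

    models: dict[str, MechanismModel] = {}
    for mid in ("TOX",) + tuple(mechanisms):
        ids, y = assembly.labels(mid)
        Xm = X_all.loc[ids, scaler.columns]
        cv = cross_validate(Xm, y, max_lv=config.max_lv, k=config.k,
                            repeats=config.repeats, seed=config.seed)
        fit = fit_pls(Z_all.loc[ids], y, n_lv=cv.n_lv)
        r = roc_from_cv(cv, y)
        thr = select_threshold(r)
        v = vip(fit)
        perm = None
        if config.permutation_B > 0:
            perm = permutation_test(
                Xm, y, n_lv=cv.n_lv, B=config.permutation_B, k=config.k,
                repeats=config.permutation_repeats, seed=config.seed,
            )
        models[mid] = MechanismModel(
            model_id=mid, fit=fit, cv=cv, roc=r, threshold=thr, vip=v,
            sample_ids=ids, y=y, permutation=perm,
            validated=(mid != "CHOL"),
        )
    return TrainedModels(models, scaler, config)


def rank_biomarkers(
    trained: TrainedModels,
    table: FeatureTable,
    vip_cut: float = 1.5,
) -> pd.DataFrame:
    """Features with VIP above the cut in any model, with the direction of
    association (sign of the mean autoscaled level in positives minus
    negatives)."""
    rows = []
    for mid, mm in trained.models.items():
        ids = mm.sample_ids
        Z = trained.scaler.transform(table.intensities.loc[ids])
        pos = np.asarray(mm.y) == 1
        for _, rec in mm.vip.iterrows():
            if rec["vip"] <= vip_cut:
                continue
            col = Z[rec["feature"]].to_numpy(float)
            delta = col[pos].mean() - col[~pos].mean()
            rows.append({"feature": rec["feature"], "model": mid,
                         "vip": float(rec["vip"]),
                         "direction": int(np.sign(delta)) if delta != 0 else 0})
    return pd.DataFrame(rows, columns=["feature", "model", "vip", "direction"])


@dataclass
class ToxicityProfile:
    """Per compound x concentration toxicity indices on the 0-1 radar scale."""

    compound: str
    concentration: float
    ypred: dict[str, float]
    calls: dict[str, bool]
    excluded: bool = False
    exclusion_reason: str | None = None
    n_wells: int = 0

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "concentration": float(self.concentration),
            "ypred": {k: float(v) for k, v in self.ypred.items()},
            "calls": {k: bool(v) for k, v in self.calls.items()},
            "excluded": bool(self.excluded),
            "exclusion_reason": self.exclusion_reason,
            "n_wells": int(self.n_wells),
        }


def predict_profiles(
    trained: TrainedModels,
    test_table: FeatureTable,
    protein_baseline: str = "blank",
    protein_fraction: float = 1.0 / 3.0,
    model_ids: tuple[str, ...] | None = None,
) -> list[ToxicityProfile]:
    """Score test compounds against the trained models.

    Low-protein exclusion runs first (when protein data is present); the test
    intensities are scaled with the *training* autoscaler; per compound and
    concentration the replicate-well mean y-predicted value of each model is
    clipped to [0, 1] and thresholded into a binary call. Conditions whose
    wells were all excluded are reported with reason "LP" and carry no calls.
    """
    if model_ids is None:
        model_ids = tuple(trained.models)
    treated = test_table.samples[test_table.samples["type"] == "treated"]
    has_protein = treated["protein"].notna().all() and (
        test_table.samples["type"].eq(protein_baseline).any()
    )
    excluded_ids: set[str] = set()
    if has_protein:
        _, rep = exclude_low_protein(test_table, baseline=protein_baseline,
                                     fraction=protein_fraction)
        excluded_ids = set(rep.samples_removed_low_protein)

    kept = [i for i in treated.index if i not in excluded_ids]
    Z = trained.scaler.transform(test_table.intensities.loc[kept]) if kept else None
    scores = {
        mid: pd.Series(trained.models[mid].fit.predict(Z), index=kept)
        for mid in model_ids
    } if kept else {mid: pd.Series(dtype=float) for mid in model_ids}

    profiles: list[ToxicityProfile] = []
    for (compound, conc), grp in treated.groupby(["compound", "concentration"],
                                                 sort=True):
        wells = [i for i in grp.index if i not in excluded_ids]
        if not wells:
            profiles.append(
                ToxicityProfile(str(compound), float(conc), {}, {},
                                excluded=True, exclusion_reason="LP",
                                n_wells=0)
            )
            continue
        ypred = {
            mid: float(np.clip(scores[mid].loc[wells].mean(), 0.0, 1.0))
            for mid in model_ids
        }
        calls = {
            mid: bool(ypred[mid] >= trained.models[mid].threshold)
            for mid in model_ids
        }
        profiles.append(
            ToxicityProfile(str(compound), float(conc), ypred, calls,
                            n_wells=len(wells))
        )
    return profiles


def concordance_summary(
    profiles: list[ToxicityProfile],
    literature_labels: dict[str, str],
    mechanisms: tuple[str, ...] = MECHANISMS,
) -> pd.DataFrame:
    """Per-concentration agreement with the literature.

    For each tested concentration: the fraction of (non-excluded) toxic
    compounds whose literature mechanism is among the positive mechanism
    calls, and the fraction of toxic compounds called TOX-positive.
    """
    rows = []
    concs = sorted({p.concentration for p in profiles})
    for conc in concs:
        here = [p for p in profiles
                if p.concentration == conc and not p.excluded
                and literature_labels.get(p.compound) in mechanisms]
        if not here:
            rows.append({"concentration": conc, "n": 0,
                         "mechanism_concordance_pct": np.nan,
                         "tox_positive_pct": np.nan})
            continue
        mech_hits = [
            p.calls.get(literature_labels[p.compound], False) for p in here
        ]
        tox_hits = [p.calls.get("TOX", False) for p in here]
        rows.append({
            "concentration": conc,
            "n": len(here),
            "mechanism_concordance_pct": 100.0 * float(np.mean(mech_hits)),
            "tox_positive_pct": 100.0 * float(np.mean(tox_hits)),
        })
    return pd.DataFrame(rows)


def export_radar(
    profiles: list[ToxicityProfile],
    path,
    axes: tuple[str, ...] = RADAR_AXES,
    render: bool = False,
) -> dict:
    """Write per-compound radar data (one polygon of axis values per
    concentration) as JSON; optionally render polar charts as PNG files
    next to the JSON."""
    if not profiles:
        raise ValidationError("no profiles to export")
    data: dict[str, dict] = {}
    for p in profiles:
        entry = data.setdefault(p.compound, {"axes": list(axes),
                                             "concentrations": []})
        entry["concentrations"].append({
            "concentration": p.concentration,
            "values": [p.ypred.get(a) for a in axes],
            "excluded": p.excluded,
        })
    for entry in data.values():
        entry["concentrations"].sort(key=lambda c: c["concentration"])
    write_json(data, path)
    if render:
        _render_radar(data, Path(path).parent, axes)
    return data


def _render_radar(data: dict, outdir: Path, axes) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    angles = np.linspace(0, 2 * np.pi, len(axes), endpoint=False)
    for compound, entry in data.items():
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
        for conc in entry["concentrations"]:
            if conc["excluded"]:
                continue
            vals = np.array([v if v is not None else 0.0 for v in conc["values"]])
            ax.plot(np.append(angles, angles[0]), np.append(vals, vals[0]),
                    label=f"{conc['concentration']:g} uM")
        ax.set_xticks(angles)
        ax.set_xticklabels(axes)
        ax.set_ylim(0, 1)
        ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=7)
        ax.set_title(compound)
        fig.savefig(outdir / f"radar_{compound}.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
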