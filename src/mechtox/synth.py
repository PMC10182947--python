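"""Synthetic untargeted-metabolomics study generator with planted ground truth.

Emulates the structure of an in vitro hepatotoxicity metabolomics study on
HepG2-like cultures: multi-batch injection sequences with a pooled QC sample
injected every ``qc_every`` injections (each batch starting and ending with a
QC), cell-free blanks, non-treated controls, non-toxic compounds and
mechanism-labelled hepatotoxicants incubated either at their IC10/IC50
(training design) or at a fixed concentration ladder (test design).

The signal model works on the natural-log scale and is exponentiated at the
end:

``log x = baseline_f + batch_{b,f} + drift_{b,f}(order) + treatment + noise``

* per-feature log-normal baselines;
* smooth multiplicative within-batch drift: a unit-variance Gaussian-process
  draw per feature (squared-exponential kernel over injection order, shared
  Cholesky factor per batch) scaled by ``drift_amplitude`` — smooth by
  construction, hence recoverable by regression on injection order;
* between-batch scale shifts: per (batch, feature) log-normal factors;
* mechanism-specific marker perturbations: each planted signature shifts its
  marker features by ``direction * effect_size * effect_reference_sd *
  activation`` log units. Two saturating two-parameter log-logistic dose-response curves
  are planted per compound: the mechanism-specific response (anchored at
  (IC10, 0.5) and (IC50, 0.9) — mechanism-linked metabolic alterations are
  appreciable already at the low toxic concentration and reinforced at the
  IC50) and the general cytotoxic response (anchored at (IC10, 0.1) and
  (IC50, 0.5), the MTT-derived curve);
* a shared general-toxicity signature growing with the cytotoxic response,
  which also drives the protein decline;
* log-normal within-condition noise with log-sd ``rsd_noise``;
* per-sample protein content declining linearly with activation.

All randomness derives from one master seed; the same inputs reproduce the
study bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    MECHANISMS,
    FeatureTable,
    Pathway,
    PathwayDB,
    ValidationError,
    write_json,
)

LOGIT_01 = float(np.log(0.1 / 0.9))  # logit of 10% activation


@dataclass(frozen=True)
class CompoundSpec:
    """A study compound with its literature mechanism(s) and potency.

    ``ic10``/``ic50`` are the concentrations (uM) reducing the MTT viability
    readout by 10%/50%; ``max_conc`` caps the tested concentration (solubility).
    """

    name: str
    mechanism_primary: str
    ic10: float
    ic50: float
    mechanism_secondary: str | None = None
    max_conc: float = float("inf")

    def __post_init__(self) -> None:
        if self.mechanism_primary not in MECHANISMS + ("NT",):
            raise ValidationError(
                f"{self.name}: unknown primary mechanism {self.mechanism_primary!r}"
            )
        if self.mechanism_secondary is not None and self.mechanism_secondary not in (
            MECHANISMS + ("NA",)
        ):
            raise ValidationError(
                f"{self.name}: unknown secondary mechanism {self.mechanism_secondary!r}"
            )
        if not self.ic10 < self.ic50:
            raise ValidationError(f"{self.name}: requires ic10 < ic50")
        if not self.max_conc > 0:
            raise ValidationError(f"{self.name}: max_conc must be > 0")

    def _loglogistic(self, concentration: float, at_ic10: float,
                     at_ic50: float) -> float:
        """Two-parameter log-logistic through (ic10, at_ic10), (ic50, at_ic50)."""
        if self.mechanism_primary == "NT" or concentration <= 0:
            return 0.0
        l10, l50 = np.log(at_ic10 / (1 - at_ic10)), np.log(at_ic50 / (1 - at_ic50))
        slope = (l50 - l10) / (np.log10(self.ic50) - np.log10(self.ic10))
        z = l50 + slope * (np.log10(concentration) - np.log10(self.ic50))
        return float(1.0 / (1.0 + np.exp(-z)))

    def activation(self, concentration: float) -> float:
        """General cytotoxic-effect activation in [0, 1): log-logistic through
        (ic10, 0.1) and (ic50, 0.5) — the MTT-anchored dose-response. Drives
        the shared general-toxicity signature and the protein decline.
        Non-toxic compounds activate nothing."""
        return self._loglogistic(concentration, 0.1, 0.5)

    def mechanism_activation(self, concentration: float) -> float:
        """Mechanism-specific response in [0, 1): log-logistic through
        (ic10, 0.5) and (ic50, 0.9). Mechanism-linked metabolic alterations
        precede overt cytotoxicity — appreciable at the low toxic
        concentration and reinforced at the IC50."""
        return self._loglogistic(concentration, 0.5, 0.9)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated study.

    ``design_kind`` is ``train_ic`` (each toxic compound at its IC10 and IC50)
    or ``test_fixed`` (every compound at ``concentrations_fixed``, capped at
    its ``max_conc``). QCs are injected every ``qc_every`` injections and each
    batch begins and ends with a QC.
    """

    compounds: tuple[CompoundSpec, ...]
    n_batches: int = 4
    qc_every: int = 8
    n_blanks_per_batch: int = 2
    n_controls_per_batch: int = 4
    replicates_per_condition: int = 4
    design_kind: str = "train_ic"
    concentrations_fixed: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)

    def __post_init__(self) -> None:
        if self.qc_every < 2:
            raise ValidationError("qc_every must be >= 2")
        if self.replicates_per_condition < 2:
            raise ValidationError("replicates_per_condition must be >= 2")
        if self.design_kind not in ("train_ic", "test_fixed"):
            raise ValidationError(f"unknown design_kind {self.design_kind!r}")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")
        names = [c.name for c in self.compounds]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValidationError(f"duplicated compound name(s): {sorted(dup)}")

    def conditions(self) -> list[tuple[CompoundSpec, float]]:
        """(compound, concentration) pairs of the treated conditions."""
        out: list[tuple[CompoundSpec, float]] = []
        for c in self.compounds:
            if self.design_kind == "train_ic":
                concs = [min(c.ic10, c.max_conc), min(c.ic50, c.max_conc)]
            else:
                concs = [min(x, c.max_conc) for x in self.concentrations_fixed]
            for conc in dict.fromkeys(concs):  # unique, order-preserving
                out.append((c, float(conc)))
        return out


@dataclass(frozen=True)
class SignatureSpec:
    """Planted metabolic signature of one hepatotoxicity mechanism.

    ``effect_size`` is the standardized marker shift at full activation, in
    units of the generator's reference log-SD (``effect_reference_sd``, which
    equals the default within-condition noise). The default of 3.0 realizes a
    ~1.5 SD shift at the IC10 of the mechanism response (activation 0.5).
    ``general_tox_markers`` contribute to the shared general-toxicity
    signature; the generator takes the union over all signatures.
    """

    mechanism: str
    marker_features: tuple[str, ...]
    directions: tuple[int, ...]
    effect_size: float = 3.0
    general_tox_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown signature mechanism {self.mechanism!r}")
        if len(self.marker_features) == 0:
            raise ValidationError(f"{self.mechanism}: empty marker set")
        if len(self.directions) != len(self.marker_features):
            raise ValidationError(f"{self.mechanism}: directions/markers length mismatch")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValidationError(f"{self.mechanism}: directions must be +1/-1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Nuisance-structure parameters of the generator.

    Defaults emulate routine cellular LC-MS variability: ~15% within-condition
    CV, ~15% smooth within-batch drift, ~20% between-batch scale shifts and
    blanks at 5% of the biological signal, so that the standard QC-RSD,
    blank-ratio and protein filters all have known planted truth.
    """

    n_features: int = 500
    baseline_log_mean: float = 11.5
    baseline_log_sd: float = 1.0
    drift_amplitude: float = 0.15
    drift_smoothness: float = 20.0  # length-scale in injections
    batch_scale_sd: float = 0.2
    blank_fraction: float = 0.05
    rsd_noise: float = 0.15
    protein_baseline: float = 200.0  # ug per well
    protein_decline: float = 0.5  # fraction lost at full activation
    protein_cv: float = 0.03
    #: the log-intensity unit in which effect sizes are expressed ("one SD");
    #: equals the default rsd_noise so effects read as within-condition SD
    #: multiples under default noise, yet survive in zero-noise limits
    effect_reference_sd: float = 0.15
    general_effect_size: float = 3.0
    secondary_strength: float = 0.5  # secondary-mechanism activation fraction
    annotated_fraction: float = 0.4
    seed: int = 0
    #: randomness of the measured feature panel itself (baselines, m/z, RT,
    #: annotation). Two studies acquired on the same assay share it; defaults
    #: to ``seed``.
    assay_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("drift_amplitude", "batch_scale_sd", "rsd_noise", "protein_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.protein_decline <= 1:
            raise ValidationError("protein_decline must be in [0, 1]")


def injection_sequence(n_study: int, qc_every: int) -> list[str]:
    """Injection-type sequence for one batch: a QC first, a QC after every
    ``qc_every - 1`` study injections, and a final closing QC."""
    seq: list[str] = ["qc"]
    placed = 0
    while placed < n_study:
        take = min(qc_every - 1, n_study - placed)
        seq.extend(["study"] * take)
        placed += take
        seq.append("qc")
    return seq


def _smooth_drift(rng: np.random.Generator, orders: np.ndarray, n_features: int,
                  length_scale: float) -> np.ndarray:
    """Unit-variance smooth Gaussian-process draws over injection order,
    one curve per feature (features x orders)."""
    d = orders[:, None] - orders[None, :]
    k = np.exp(-0.5 * (d / max(length_scale, 1e-6)) ** 2)
    k[np.diag_indices_from(k)] += 1e-8
    chol = np.linalg.cholesky(k)
    z = rng.standard_normal((n_features, len(orders)))
    return z @ chol.T


def generate_study(
    design: StudyDesign,
    signatures: Sequence[SignatureSpec],
    config: GeneratorConfig,
) -> FeatureTable:
    """Simulate a complete study and return its feature table.

    Sample metadata records batch, injection order, type, compound,
    concentration, protein content and the planted ground truth: one
    ``activation_<mechanism>`` column per modelled mechanism plus
    ``activation_general``.
    """
    mech_in_design = {c.mechanism_primary for c in design.compounds} - {"NT"}
    for sig in signatures:
        if sig.mechanism not in mech_in_design:
            raise ValidationError(
                f"signature for {sig.mechanism} but no compound in the design "
                f"has that primary mechanism"
            )
        for fid in sig.marker_features:
            _check_feature_id(fid, config.n_features)
        for fid in sig.general_tox_markers:
            _check_feature_id(fid, config.n_features)

    master = np.random.default_rng(config.seed)
    (r_assign, r_batch, r_drift, r_noise, r_prot) = master.spawn(5)
    assay_seed = config.seed if config.assay_seed is None else config.assay_seed
    r_feat = np.random.default_rng(assay_seed).spawn(1)[0]

    feature_ids = [f"F{i:04d}" for i in range(config.n_features)]
    baseline = r_feat.normal(config.baseline_log_mean, config.baseline_log_sd,
                             config.n_features)
    features = _feature_metadata(r_feat, feature_ids, signatures, config)

    sig_by_mech = {s.mechanism: s for s in signatures}
    fidx = {f: i for i, f in enumerate(feature_ids)}
    general_markers = sorted({m for s in signatures for m in s.general_tox_markers})

    # treated conditions distributed across batches as replicate blocks
    conditions = design.conditions()
    order = r_assign.permutation(len(conditions))
    batch_of_condition = {int(order[i]): i % design.n_batches for i in range(len(order))}

    # build per-batch study-sample descriptor lists
    batches: list[list[dict]] = [[] for _ in range(design.n_batches)]
    for ci, (comp, conc) in enumerate(conditions):
        b = batch_of_condition[ci]
        for rep in range(design.replicates_per_condition):
            batches[b].append(
                dict(type="treated", compound=comp.name, concentration=conc,
                     spec=comp, rep=rep)
            )
    for b in range(design.n_batches):
        for rep in range(design.n_controls_per_batch):
            batches[b].append(dict(type="control", compound=None,
                                   concentration=None, spec=None, rep=rep))
        for rep in range(design.n_blanks_per_batch):
            batches[b].append(dict(type="blank", compound=None,
                                   concentration=None, spec=None, rep=rep))

    # per-sample treatment effects (log scale), noise-free, used for both
    # biological samples and the pooled-QC mean profile
    def treatment_shift(spec: CompoundSpec | None, conc: float | None) -> tuple[np.ndarray, dict]:
        shift = np.zeros(config.n_features)
        acts = {m: 0.0 for m in MECHANISMS}
        general = 0.0
        if spec is not None and spec.mechanism_primary != "NT":
            general = spec.activation(conc)
            act = spec.mechanism_activation(conc)
            acts[spec.mechanism_primary] = act
            if spec.mechanism_secondary not in (None, "NA"):
                acts[spec.mechanism_secondary] = max(
                    acts[spec.mechanism_secondary], config.secondary_strength * act
                )
            for mech, level in acts.items():
                sig = sig_by_mech.get(mech)
                if sig is None or level == 0.0:
                    continue
                for fid, d in zip(sig.marker_features, sig.directions):
                    shift[fidx[fid]] += (d * sig.effect_size
                                         * config.effect_reference_sd * level)
            for fid in general_markers:
                shift[fidx[fid]] += (config.general_effect_size
                                     * config.effect_reference_sd * general)
        acts["general"] = general
        return shift, acts

    # pooled QC profile: mean linear-scale intensity over all biological samples
    bio_profiles = []
    for b in range(design.n_batches):
        for s in batches[b]:
            if s["type"] == "blank":
                continue
            shift, _ = treatment_shift(s["spec"], s["concentration"])
            bio_profiles.append(np.exp(baseline + shift))
    qc_log_profile = np.log(np.mean(bio_profiles, axis=0))

    batch_effect = (r_batch.normal(0.0, config.batch_scale_sd,
                                   (design.n_batches, config.n_features))
                    if config.batch_scale_sd > 0
                    else np.zeros((design.n_batches, config.n_features)))

    rows, meta = [], []
    for b in range(design.n_batches):
        study = list(r_assign.permutation(len(batches[b])))  # random injection order
        seq = injection_sequence(len(study), design.qc_every)
        orders = np.arange(1, len(seq) + 1, dtype=float)
        if config.drift_amplitude > 0:
            drift = config.drift_amplitude * _smooth_drift(
                r_drift, orders, config.n_features, config.drift_smoothness
            )  # features x injections
        else:
            drift = np.zeros((config.n_features, len(seq)))

        qc_counter, study_ptr = 0, 0
        for pos, kind in enumerate(seq):
            inj = pos + 1
            d = drift[:, pos]
            if kind == "qc":
                qc_counter += 1
                log_x = qc_log_profile + batch_effect[b] + d
                sid = f"B{b + 1}_QC{qc_counter:02d}"
                info = dict(type="qc", compound=None, concentration=None,
                            batch=b + 1, injection_order=inj,
                            mechanism_label=None, protein=np.nan)
                acts = {m: 0.0 for m in MECHANISMS} | {"general": 0.0}
            else:
                s = batches[b][study[study_ptr]]
                study_ptr += 1
                if s["type"] == "blank":
                    log_x = (baseline + np.log(config.blank_fraction)
                             + batch_effect[b] + d)
                    sid = f"B{b + 1}_BLK{s['rep'] + 1:02d}"
                    prot = config.protein_baseline
                    info = dict(type="blank", compound=None, concentration=None,
                                batch=b + 1, injection_order=inj,
                                mechanism_label=None, protein=prot)
                    acts = {m: 0.0 for m in MECHANISMS} | {"general": 0.0}
                elif s["type"] == "control":
                    log_x = baseline + batch_effect[b] + d
                    sid = f"B{b + 1}_CTRL{s['rep'] + 1:02d}"
                    prot = config.protein_baseline
                    info = dict(type="control", compound=None, concentration=None,
                                batch=b + 1, injection_order=inj,
                                mechanism_label=None, protein=prot)
                    acts = {m: 0.0 for m in MECHANISMS} | {"general": 0.0}
                else:
                    spec: CompoundSpec = s["spec"]
                    shift, acts = treatment_shift(spec, s["concentration"])
                    log_x = baseline + shift + batch_effect[b] + d
                    prot = config.protein_baseline * (
                        1.0 - config.protein_decline * acts["general"]
                    )
                    sid = (f"B{b + 1}_{spec.name}_c{s['concentration']:g}"
                           f"_r{s['rep'] + 1}")
                    info = dict(type="treated", compound=spec.name,
                                concentration=s["concentration"], batch=b + 1,
                                injection_order=inj,
                                mechanism_label=spec.mechanism_primary,
                                protein=prot)
            noise = (r_noise.normal(0.0, config.rsd_noise, config.n_features)
                     if config.rsd_noise > 0 else 0.0)
            if info["type"] == "treated" and config.protein_cv > 0:
                info["protein"] *= float(
                    np.exp(r_prot.normal(0.0, config.protein_cv))
                )
            rows.append(np.exp(log_x + noise))
            meta.append(
                info | {f"activation_{m}": acts[m] for m in MECHANISMS}
                | {"activation_general": acts["general"], "id": sid}
            )

    samples = pd.DataFrame(meta).set_index("id")
    samples.index.name = None
    intens = pd.DataFrame(np.array(rows), index=samples.index, columns=feature_ids)
    ids = samples.index
    if ids.duplicated().any():
        raise ValidationError(
            f"overlapping sample ids: {ids[ids.duplicated()].unique().tolist()}"
        )
    return FeatureTable(intens, samples, features)


def _check_feature_id(fid: str, n_features: int) -> None:
    try:
        idx = int(fid.lstrip("F"))
    except ValueError:
        raise ValidationError(f"feature id {fid!r} not of the form F<number>")
    if not 0 <= idx < n_features:
        raise ValidationError(f"signature feature {fid} outside [0, {n_features})")


def _feature_metadata(rng: np.random.Generator, feature_ids: list[str],
                      signatures: Sequence[SignatureSpec],
                      config: GeneratorConfig) -> pd.DataFrame:
    n = len(feature_ids)
    must_annotate = {f for s in signatures for f in s.marker_features}
    must_annotate |= {f for s in signatures for f in s.general_tox_markers}
    n_annot = max(len(must_annotate), int(round(config.annotated_fraction * n)))
    pool = [f for f in feature_ids if f not in must_annotate]
    extra = list(rng.choice(pool, size=max(0, n_annot - len(must_annotate)),
                            replace=False)) if pool else []
    annotated = sorted(must_annotate) + sorted(extra)
    hmdb = {f: f"SYNDB{int(f[1:]):05d}" for f in annotated}  # synthetic ids
    return pd.DataFrame(
        {
            "mz": rng.uniform(70, 1200, n),
            "rt": rng.uniform(30, 600, n),
            "method": np.where(np.arange(n) % 2 == 0, "method1", "method2"),
            "hmdb_id": [hmdb.get(f) for f in feature_ids],
            "name": [None] * n,
        },
        index=pd.Index(feature_ids),
    )


def default_signatures(
    n_features: int = 500,
    markers_per_mechanism: int = 12,
    n_general_markers: int = 15,
    mechanisms: Sequence[str] = MECHANISMS,
    effect_size: float = 3.0,
    general_effect_size: float = 3.0,
    seed: int = 0,
) -> list[SignatureSpec]:
    """Disjoint marker sets per mechanism plus one shared general-toxicity set.

    Marker directions emulate known biology loosely: each mechanism gets a mix
    of decreased (e.g. GSH-like depletion under oxidative stress) and
    increased (e.g. acetyl-polyamine-like accumulation) markers.
    """
    rng = np.random.default_rng(seed)
    needed = markers_per_mechanism * len(mechanisms) + n_general_markers
    if needed > n_features:
        raise ValidationError("not enough features for the requested signatures")
    chosen = rng.choice(n_features, size=needed, replace=False)
    blocks = np.split(chosen, [markers_per_mechanism * (i + 1)
                               for i in range(len(mechanisms))])
    general = tuple(f"F{i:04d}" for i in sorted(blocks[-1]))
    sigs = []
    for mech, block in zip(mechanisms, blocks):
        markers = tuple(f"F{i:04d}" for i in sorted(block))
        directions = tuple(int(d) for d in rng.choice([-1, 1], size=len(markers)))
        sigs.append(
            SignatureSpec(mech, markers, directions, effect_size=effect_size,
                          general_tox_markers=general)
        )
    # keep the general effect size consistent with GeneratorConfig default
    del general_effect_size
    return sigs


def generate_pathway_db(
    n_pathways: int,
    sizes: tuple[int, int],
    annotated_features: Sequence[str],
    seed: int,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
) -> PathwayDB:
    """Random metabolite-set database over annotation keys, standing in for a
    curated pathway resource.

    Every pathway gets a connected random graph over its members for
    topology-impact scoring. When ``marker_sets`` maps mechanisms to marker
    annotation keys, one extra pathway per mechanism is planted that contains
    ~80% of that mechanism's markers, so enrichment has known truth.
    """
    lo, hi = sizes
    if lo < 4:
        raise ValidationError("minimum pathway size must be >= 4 (the >3-hits "
                              "filter must be exercisable)")
    annotated = sorted(set(annotated_features))
    if n_pathways > 0 and len(annotated) < lo:
        raise ValidationError("fewer annotated features than the minimum pathway size")
    rng = np.random.default_rng(seed)
    pathways: list[Pathway] = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(annotated, size=size, replace=False))
        pathways.append(
            Pathway(f"P{i:03d}", f"synthetic pathway {i}", frozenset(members),
                    _random_connected_graph(rng, members))
        )
    if marker_sets:
        for j, (mech, markers) in enumerate(sorted(marker_sets.items())):
            markers = sorted(set(markers) & set(annotated))
            if not markers:
                raise ValidationError(f"no annotated markers for mechanism {mech}")
            take = max(4, int(round(0.8 * len(markers))))
            members = sorted(rng.choice(markers, size=min(take, len(markers)),
                                        replace=False))
            filler_pool = sorted(set(annotated) - set(members))
            n_fill = min(max(0, lo - len(members)) + 2, len(filler_pool))
            members = sorted(members
                             + list(rng.choice(filler_pool, size=n_fill,
                                               replace=False)))
            pathways.append(
                Pathway(f"PM{j:02d}", f"synthetic {mech} pathway",
                        frozenset(members),
                        _random_connected_graph(rng, members))
            )
    return PathwayDB(pathways)


def _random_connected_graph(rng: np.random.Generator, members: list[str]) -> nx.Graph:
    """Random spanning tree plus a few chords — connected by construction."""
    g = nx.Graph()
    g.add_nodes_from(members)
    shuffled = list(rng.permutation(members))
    for i in range(1, len(shuffled)):
        j = int(rng.integers(0, i))
        g.add_edge(shuffled[i], shuffled[j])
    n_extra = max(0, len(members) // 4)
    for _ in range(n_extra):
        a, b = rng.choice(members, size=2, replace=False)
        if a != b:
            g.add_edge(a, b)
    return g


def write_ground_truth(
    signatures: Sequence[SignatureSpec], table: FeatureTable, path
) -> None:
    """Serialize planted signatures and per-sample activations as JSON."""
    acts = {
        sid: {
            c.removeprefix("activation_"): float(table.samples.loc[sid, c])
            for c in table.samples.columns
            if c.startswith("activation_")
        }
        for sid in table.sample_ids
    }
    payload = {
        "signatures": [
            {
                "mechanism": s.mechanism,
                "marker_features": list(s.marker_features),
                "directions": list(s.directions),
                "effect_size": s.effect_size,
                "general_tox_markers": list(s.general_tox_markers),
            }
            for s in signatures
        ],
        "activations": acts,
    }
    write_json(payload, path)
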