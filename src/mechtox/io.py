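"""Data model and readers/writers for feature tables and pathway databases.

The central container is :class:`FeatureTable`: a samples x features peak-area
matrix with two metadata frames (one per sample, one per LC-MS feature).
Samples are rows; features are columns; sample metadata lives in a sidecar
table keyed by sample id, which keeps the intensity matrix rectangular and
easy to consume with standard tooling.

Missing intensities are permitted (peak filling is upstream of this package)
and are encoded as empty cells on disk / NaN in memory. Downstream operations
state their own missing-data policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: closed vocabulary of mechanism labels
MECHANISMS = ("OS", "MI", "APT", "ST", "CHOL")
MECHANISM_LABELS = MECHANISMS + ("NT", "NA")
SAMPLE_TYPES = ("blank", "qc", "control", "treated")

SAMPLE_COLUMNS = (
    "type",
    "compound",
    "concentration",
    "batch",
    "injection_order",
    "mechanism_label",
    "protein",
)
FEATURE_COLUMNS = ("mz", "rt", "method", "hmdb_id", "name")


class ValidationError(ValueError):
    """Raised when a table or database violates its structural invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class FeatureTable:
    """Samples x features intensity matrix plus per-sample and per-feature metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with feature ids as columns. Values are
        non-negative peak areas (arbitrary units); NaN marks a missing peak.
    samples
        DataFrame indexed by sample id. Required columns: ``type`` (one of
        blank/qc/control/treated), ``compound``, ``concentration`` (uM),
        ``batch``, ``injection_order``, ``mechanism_label``, ``protein`` (ug).
        Extra columns (e.g. planted ground-truth activations) are preserved.
    features
        DataFrame indexed by feature id. Required columns: ``mz`` (Da), ``rt``
        (seconds), ``method``, ``hmdb_id``, ``name``.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ids = self.intensities.index
        dup = ids[ids.duplicated()].unique().tolist()
        _require(not dup, f"duplicated sample id(s): {dup}")
        fdup = self.intensities.columns[self.intensities.columns.duplicated()]
        _require(len(fdup) == 0, f"duplicated feature id(s): {list(fdup.unique())}")
        _require(
            list(self.samples.index) == list(ids),
            "sample metadata index does not match intensity matrix rows",
        )
        _require(
            list(self.features.index) == list(self.intensities.columns),
            "feature metadata index does not match intensity matrix columns",
        )
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        _require(not missing_cols, f"sample metadata lacks column(s): {missing_cols}")
        missing_cols = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        _require(not missing_cols, f"feature metadata lacks column(s): {missing_cols}")

        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            bad = self.intensities.columns[(vals < 0).any(axis=0)][:5].tolist()
            raise ValidationError(f"negative intensities in feature(s): {bad}")

        bad_type = self.samples.loc[~self.samples["type"].isin(SAMPLE_TYPES)]
        _require(bad_type.empty, f"invalid sample type(s) for: {bad_type.index.tolist()}")

        treated = self.samples[self.samples["type"] == "treated"]
        no_cmpd = treated[treated["compound"].isna()].index.tolist()
        _require(not no_cmpd, f"treated sample(s) without compound: {no_cmpd}")
        no_conc = treated[treated["concentration"].isna()].index.tolist()
        _require(not no_conc, f"treated sample(s) without concentration: {no_conc}")

        labels = self.samples["mechanism_label"].dropna()
        bad = labels[~labels.isin(MECHANISM_LABELS)].unique().tolist()
        _require(not bad, f"unknown mechanism label(s): {bad}")

        for batch, grp in self.samples.groupby("batch"):
            orders = grp["injection_order"]
            dup = orders[orders.duplicated()].tolist()
            _require(not dup, f"batch {batch}: duplicated injection order(s) {dup}")

        mz = self.features["mz"].to_numpy(dtype=float)
        _require(bool(np.all(mz > 0)), "feature m/z must be > 0")
        rt = self.features["rt"].to_numpy(dtype=float)
        _require(bool(np.all(rt >= 0)), "feature RT must be >= 0")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def select_samples(self, ids: Sequence[str] | pd.Index) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(
            self.intensities.loc[ids].copy(),
            self.samples.loc[ids].copy(),
            self.features.copy(),
        )

    def of_type(self, *types: str) -> "FeatureTable":
        mask = self.samples["type"].isin(types)
        return self.select_samples(self.samples.index[mask])

    def drop_features(self, ids: Iterable[str]) -> "FeatureTable":
        ids = set(ids)
        keep = [f for f in self.feature_ids if f not in ids]
        return FeatureTable(
            self.intensities[keep].copy(),
            self.samples.copy(),
            self.features.loc[keep].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.samples.copy(), self.features.copy()
        )

    def annotation_keys(self) -> pd.Series:
        """Per-feature matching key for pathway analysis: HMDB id when present,
        else the feature id itself."""
        keys = self.features["hmdb_id"].copy()
        keys = keys.where(keys.notna(), pd.Series(self.feature_ids, index=keys.index))
        return keys

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, FeatureTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.intensities, other.intensities)
            pd.testing.assert_frame_equal(self.samples, other.samples)
            pd.testing.assert_frame_equal(self.features, other.features)
        except AssertionError:
            return False
        return True


# -- feature table persistence -------------------------------------------


def _paths(stem: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(stem)
    return (
        stem.with_suffix(".intensities.tsv"),
        stem.with_suffix(".samples.tsv"),
        stem.with_suffix(".features.tsv"),
    )


def write_feature_table(table: FeatureTable, stem: str | Path) -> list[Path]:
    """Write a table as three TSV files ``<stem>.{intensities,samples,features}.tsv``.

    Writers are deterministic (column order preserved) and round-trip to full
    float precision; missing intensities become empty cells.
    """
    pi, ps, pf = _paths(stem)
    pi.parent.mkdir(parents=True, exist_ok=True)
    table.intensities.to_csv(pi, sep="\t", index_label="sample_id")
    table.samples.to_csv(ps, sep="\t", index_label="sample_id")
    table.features.to_csv(pf, sep="\t", index_label="feature_id")
    return [pi, ps, pf]


def read_feature_table(stem: str | Path) -> FeatureTable:
    """Read a table written by :func:`write_feature_table`.

    Malformed input is rejected with row/column context rather than coerced.
    """
    pi, ps, pf = _paths(stem)
    intens = pd.read_csv(pi, sep="\t", index_col="sample_id")
    try:
        intens = intens.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric intensity cell in {pi}: {exc}") from exc
    samples = pd.read_csv(ps, sep="\t", index_col="sample_id")
    features = pd.read_csv(pf, sep="\t", index_col="feature_id")
    samples.index = samples.index.astype(str)
    features.index = features.index.astype(str)
    intens.index = intens.index.astype(str)
    intens.columns = intens.columns.astype(str)
    for frame in (intens, samples, features):
        frame.index.name = None
    intens.columns.name = None
    return FeatureTable(intens, samples, features)


def combine_methods(t1: FeatureTable, t2: FeatureTable) -> FeatureTable:
    """Concatenate the feature columns of two tables acquired on the same samples
    (e.g. two chromatographic methods). No deduplication: the combined feature
    count is the sum of the parts.
    """
    s1, s2 = set(t1.sample_ids), set(t2.sample_ids)
    if s1 != s2:
        unmatched = sorted(s1 ^ s2)
        raise ValidationError(f"sample sets differ; unmatched id(s): {unmatched}")
    clash = sorted(set(t1.feature_ids) & set(t2.feature_ids))
    if clash:
        raise ValidationError(f"feature id(s) present in both tables: {clash[:5]}")
    t2i = t2.intensities.loc[t1.sample_ids]
    intens = pd.concat([t1.intensities, t2i], axis=1)
    features = pd.concat([t1.features, t2.features], axis=0)
    return FeatureTable(intens, t1.samples.copy(), features)


# -- pathway database -----------------------------------------------------


@dataclass
class Pathway:
    id: str
    name: str
    members: frozenset
    graph: nx.Graph | None = None

    def __post_init__(self) -> None:
        _require(len(self.members) > 0, f"pathway {self.id}: empty member set")
        if self.graph is not None:
            extra = set(self.graph.nodes) - set(self.members)
            _require(
                not extra,
                f"pathway {self.id}: graph node(s) not in member set: {sorted(extra)}",
            )


@dataclass
class PathwayDB:
    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        dup = {i for i in ids if ids.count(i) > 1}
        _require(not dup, f"duplicated pathway id(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]


def read_pathway_db(gmt_path: str | Path, edges_path: str | Path | None = None) -> PathwayDB:
    """Read pathway membership from a GMT file and, optionally, per-pathway
    undirected graphs from a TSV edge list (columns: pathway, node_a, node_b)."""
    gmt_path = Path(gmt_path)
    pathways: dict[str, Pathway] = {}
    for lineno, line in enumerate(gmt_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{gmt_path}:{lineno}: GMT line needs id, name and >=1 member"
            )
        pid, name, *members = parts
        if pid in pathways:
            raise ValidationError(f"{gmt_path}:{lineno}: duplicated pathway id {pid}")
        pathways[pid] = Pathway(pid, name, frozenset(members))

    if edges_path is not None:
        graphs: dict[str, nx.Graph] = {}
        for lineno, line in enumerate(Path(edges_path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{edges_path}:{lineno}: expected 3 columns (pathway, node_a, node_b)"
                )
            pid, a, b = parts
            if pid not in pathways:
                raise ValidationError(f"{edges_path}:{lineno}: unknown pathway {pid}")
            for node in (a, b):
                if node not in pathways[pid].members:
                    raise ValidationError(
                        f"{edges_path}:{lineno}: edge node {node!r} is not a member "
                        f"of pathway {pid}"
                    )
            graphs.setdefault(pid, nx.Graph()).add_edge(a, b)
        for pid, g in graphs.items():
            p = pathways[pid]
            pathways[pid] = Pathway(p.id, p.name, p.members, g)

    return PathwayDB(list(pathways.values()))


def write_pathway_db(db: PathwayDB, gmt_path: str | Path, edges_path: str | Path | None = None) -> None:
    gmt_path = Path(gmt_path)
    gmt_path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for p in db:
        members = "\t".join(sorted(p.members))
        lines.append(f"{p.id}\t{p.name}\t{members}")
    gmt_path.write_text("\n".join(lines) + ("\n" if lines else ""))
    if edges_path is not None:
        rows = []
        for p in db:
            if p.graph is None:
                continue
            for a, b in sorted(tuple(sorted(e)) for e in p.graph.edges):
                rows.append(f"{p.id}\t{a}\t{b}")
        Path(edges_path).write_text("\n".join(rows) + ("\n" if rows else ""))


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
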