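"""Feature schemas: mapping raw genomic feature values to global item codes.

Every feature owns a contiguous block of integer codes.  All but the last
code of the block encode the feature's value bins; the largest code of the
block always means "no record for this protein" (missing).  Codes are
globally unique, so a transaction — one code per feature — is a set of
items over a shared alphabet and can be mined directly.

The bundled ``yeast19`` profile covers the 19 genomic features used for
yeast protein localization (motif signals, overall-sequence properties and
whole-genome expression statistics), with global codes 1–113 and class
labels C, N, M, T, E (cytoplasm, nucleus, mitochondria, membrane,
secretory pathway).  Example: the endoplasmic-reticulum retention signal
HDEL occupies codes 82–84 — 82 absent, 83 present, 84 no record.

Numeric features (isoelectric point, expression statistics) are discretized
by quantile bin edges fitted on training data; the edges are persisted with
the model so held-out data are encoded identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from ._transactions import Transaction

MISSING = None  # raw-value marker for "no record"


@dataclass
class FeatureSpec:
    """One feature's code block.

    first_code..last_code is the inclusive global code range; the last code
    is the missing code, so the feature has (range size - 1) value bins.
    Categorical features may declare their category values in bin order;
    numeric features carry ascending bin edges (len = value bins - 1).
    """

    name: str
    kind: str  # "categorical" | "binned_numeric"
    first_code: int
    last_code: int
    categories: Optional[List] = None
    bin_edges: Optional[List[float]] = None
    description: str = ""

    def __post_init__(self):
        if self.kind not in ("categorical", "binned_numeric"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.first_code < 1 or self.last_code <= self.first_code:
            raise ValueError(
                f"{self.name}: invalid code range {self.first_code}–{self.last_code}"
            )
        if self.categories is not None and len(self.categories) != self.n_bins:
            raise ValueError(
                f"{self.name}: {len(self.categories)} categories for "
                f"{self.n_bins} value bins"
            )
        if self.bin_edges is not None:
            edges = list(self.bin_edges)
            if len(edges) != self.n_bins - 1:
                raise ValueError(
                    f"{self.name}: {len(edges)} bin edges for {self.n_bins} bins "
                    f"(need bins - 1)"
                )
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{self.name}: bin edges must be ascending")

    @property
    def missing_code(self) -> int:
        return self.last_code

    @property
    def codes(self) -> range:
        return range(self.first_code, self.last_code + 1)

    @property
    def n_bins(self) -> int:
        """Number of value bins (the missing code excluded)."""
        return self.last_code - self.first_code

    def encode(self, value) -> int:
        """Map one raw value to its global code."""
        if value is MISSING:
            return self.missing_code
        if self.kind == "categorical":
            if self.categories is not None:
                try:
                    return self.first_code + self.categories.index(value)
                except ValueError:
                    raise ValueError(
                        f"{self.name}: value {value!r} not among categories "
                        f"{self.categories}"
                    ) from None
            # without declared categories, accept a 1-based bin index
            idx = int(value)
            if not 1 <= idx <= self.n_bins:
                raise ValueError(
                    f"{self.name}: bin index {value!r} outside 1..{self.n_bins}"
                )
            return self.first_code + idx - 1
        if self.bin_edges is None:
            raise ValueError(f"{self.name}: numeric feature has no bin edges fitted")
        # left-closed, half-open bins; values below/above the edges clamp
        # into the first/last bin so encoding is total
        idx = int(np.searchsorted(self.bin_edges, value, side="right"))
        return self.first_code + idx

    def bin_index(self, code: int) -> Optional[int]:
        """1-based value-bin index of a code; None for the missing code."""
        if code not in self.codes:
            raise ValueError(f"{self.name}: code {code} outside {self.codes}")
        if code == self.missing_code:
            return None
        return code - self.first_code + 1


@dataclass
class FeatureSchema:
    """An ordered list of features with globally disjoint, contiguous codes."""

    features: List[FeatureSpec]
    class_labels: List[str] = field(default_factory=list)
    name: str = "custom"

    def __post_init__(self):
        expected = self.features[0].first_code if self.features else 1
        for f in self.features:
            if f.first_code != expected:
                raise ValueError(
                    f"feature {f.name}: codes must be contiguous; expected "
                    f"block starting at {expected}, got {f.first_code}"
                )
            expected = f.last_code + 1
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    @property
    def max_code(self) -> int:
        return self.features[-1].last_code

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_of_code(self, code: int) -> FeatureSpec:
        for f in self.features:
            if code in f.codes:
                return f
        raise ValueError(f"code {code} belongs to no feature")

    def validate_transaction(self, t: Transaction) -> None:
        """Check: one in-range code per feature, no feature repeated."""
        seen: Dict[str, int] = {}
        for code in t.items:
            f = self.feature_of_code(code)
            if f.name in seen:
                raise ValueError(
                    f"transaction {t.id}: two codes for feature {f.name} "
                    f"({seen[f.name]}, {code})"
                )
            seen[f.name] = code
        missing = [f.name for f in self.features if f.name not in seen]
        if missing:
            raise ValueError(f"transaction {t.id}: no code for {missing}")

    def fit_bin_edges(self, values_by_feature: Dict[str, Sequence[float]]) -> None:
        """Fit quantile bin edges for numeric features from training values."""
        for f in self.features:
            if f.kind == "binned_numeric" and f.name in values_by_feature:
                f.bin_edges = derive_bin_edges(
                    values_by_feature[f.name], f.n_bins
                )

    def edges_snapshot(self) -> Dict[str, list]:
        return {
            f.name: list(f.bin_edges)
            for f in self.features
            if f.bin_edges is not None
        }


@dataclass
class RawRecord:
    """Pre-discretization record: raw feature values keyed by feature name.

    Features absent from ``values`` (or mapped to None) encode as the
    feature's missing code.
    """

    id: str
    values: Dict[str, object]
    label: Optional[str] = None


def encode_record(r: RawRecord, schema: FeatureSchema) -> Transaction:
    """Discretize a raw record into a transaction (one code per feature)."""
    unknown = set(r.values) - {f.name for f in schema}
    if unknown:
        raise ValueError(f"record {r.id}: unknown features {sorted(unknown)}")
    items = [f.encode(r.values.get(f.name, MISSING)) for f in schema]
    return Transaction(r.id, items, r.label)


def decode_transaction(t: Transaction, schema: FeatureSchema) -> Dict[str, Optional[int]]:
    """Inverse view of encoding: feature name -> 1-based bin index (None =
    missing).  Round-trips the bin index of every feature."""
    schema.validate_transaction(t)
    return {
        schema.feature_of_code(code).name: schema.feature_of_code(code).bin_index(code)
        for code in t.items
    }


def derive_bin_edges(values: Sequence[float], k: int) -> List[float]:
    """Quantile bin edges producing ``k`` near-equal-occupancy bins.

    Returns k-1 strictly ascending interior cut points.  Deterministic for
    fixed input; fails when the values have fewer than ``k`` distinct
    levels (choose a smaller k).
    """
    if k < 2:
        raise ValueError("need at least 2 bins")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or np.unique(arr).size < k:
        raise ValueError(
            f"need at least {k} distinct values to derive {k} bins; "
            f"got {np.unique(arr).size} — use a smaller bin count"
        )
    edges = np.quantile(arr, np.arange(1, k) / k)
    edges = np.unique(edges)
    if edges.size != k - 1:
        raise ValueError(
            f"values too concentrated for {k} equal-occupancy bins; "
            f"use a smaller bin count"
        )
    return [float(e) for e in edges]


# ---------------------------------------------------------------------------
# Bundled yeast localization profile: 19 features, global codes 1-113.

_ABSENT_PRESENT = ["absent", "present"]

_YEAST19 = [
    # (name, kind, first, last, categories, description)
    ("MIT1", "categorical", 1, 3, ["no_cut", "cut"],
     "more than one N-terminal residue cut (mitochondrial hint)"),
    ("GLYC", "categorical", 4, 14, None,
     "number of predicted N-glycosylation sites (NXS/T)"),
    ("SIGNALP", "categorical", 15, 17, _ABSENT_PRESENT,
     "secretory signal peptide"),
    ("SIG1", "categorical", 18, 20, _ABSENT_PRESENT,
     "charged-residue + hydrophobic-stretch signal sequence"),
    ("NUC1", "categorical", 21, 27, None,
     "basic four-residue nuclear localization patterns"),
    ("PI", "binned_numeric", 28, 38, None, "isoelectric point"),
    ("TMS1", "categorical", 39, 44, None,
     "predicted transmembrane segments (GES hydrophobicity)"),
    ("MAYOUNG", "binned_numeric", 45, 55, None,
     "absolute mRNA expression (GeneChip), bins low to high"),
    ("KNOCKOUT", "categorical", 56, 58, ["viable", "lethal"],
     "knockout mutation phenotype"),
    ("MRDIASD", "binned_numeric", 59, 69, None,
     "mRNA expression fluctuation, diauxic shift"),
    ("PLMNEW1", "categorical", 70, 72, _ABSENT_PRESENT,
     "plasma membrane signal"),
    ("FARN", "categorical", 73, 75, _ABSENT_PRESENT,
     "C-terminal farnesylation site"),
    ("GGSI", "categorical", 76, 78, _ABSENT_PRESENT,
     "C-terminal geranylgeranylation site"),
    ("MIT2", "categorical", 79, 81, _ABSENT_PRESENT,
     "mitochondrial matrix import sequence"),
    ("HDEL", "categorical", 82, 84, _ABSENT_PRESENT,
     "endoplasmic reticulum retention signal (HDEL)"),
    ("NUC2", "categorical", 85, 88, None,
     "P followed by basic four-residue segment"),
    ("POX1", "categorical", 89, 91, _ABSENT_PRESENT,
     "C-terminal peroxisome import signal"),
    ("MRCYELU", "binned_numeric", 92, 102, None,
     "mRNA expression fluctuation, elutriation time series"),
    ("MRCYCSD", "binned_numeric", 103, 113, None,
     "mRNA expression fluctuation, alpha-factor arrest time series"),
]

CLASS_LABELS = ["C", "N", "M", "T", "E"]


def yeast19() -> FeatureSchema:
    """The bundled 19-feature yeast localization schema (codes 1-113)."""
    return FeatureSchema(
        [
            FeatureSpec(name, kind, first, last,
                        categories=list(cats) if cats else None,
                        description=desc)
            for name, kind, first, last, cats, desc in _YEAST19
        ],
        class_labels=list(CLASS_LABELS),
        name="yeast19",
    )


def load_schema(source) -> FeatureSchema:
    """Load a schema from a YAML path, a YAML string, or a mapping.

    Expected layout::

        name: my_schema
        class_labels: [C, N, M, T, E]
        features:
          - {name: HDEL, kind: categorical, first_code: 82, last_code: 84,
             categories: [absent, present]}

    The profile name ``yeast19`` loads the bundled yeast schema.
    """
    if isinstance(source, str) and source == "yeast19":
        return yeast19()
    if isinstance(source, dict):
        cfg = source
    else:
        text = None
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            if isinstance(source, str):
                text = source
            else:
                raise
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "features" not in cfg:
        raise ValueError("schema config must be a mapping with a 'features' list")
    for f in cfg["features"]:
        if "missing_code" in f and int(f["missing_code"]) != int(f["last_code"]):
            raise ValueError(
                f"feature {f.get('name')}: missing_code must be the range "
                f"maximum ({f['last_code']}), got {f['missing_code']}"
            )
    feats = [
        FeatureSpec(
            name=f["name"],
            kind=f.get("kind", "categorical"),
            first_code=int(f["first_code"]),
            last_code=int(f["last_code"]),
            categories=f.get("categories"),
            bin_edges=f.get("bin_edges"),
            description=f.get("description", ""),
        )
        for f in cfg["features"]
    ]
    return FeatureSchema(
        feats,
        class_labels=list(cfg.get("class_labels", [])),
        name=cfg.get("name", "custom"),
    )


def dump_schema(schema: FeatureSchema) -> str:
    """Serialize a schema to YAML (inverse of :func:`load_schema`)."""
    cfg = {
        "name": schema.name,
        "class_labels": list(schema.class_labels),
        "features": [
            {
                k: v
                for k, v in (
                    ("name", f.name),
                    ("kind", f.kind),
                    ("first_code", f.first_code),
                    ("last_code", f.last_code),
                    ("categories", f.categories),
                    ("bin_edges", f.bin_edges),
                    ("description", f.description or None),
                )
                if v is not None
            }
            for f in schema
        ],
    }
    return yaml.safe_dump(cfg, sort_keys=False)
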