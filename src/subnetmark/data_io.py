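"""Readers, writers and validated containers for every format the pipeline touches.

Expression matrices arrive as TSV (header = sample ids, first column = gene
symbol) with an optional two-column class file; interactions as Cytoscape SIF
or a two-column TSV; clinical data as a TSV with named columns; annotation
sets as GMT. Subnetwork panels are written as GMT plus a JSON sidecar that
carries the up/down partitions GMT cannot express.

Gene symbols are matched case-sensitively after whitespace trimming; no alias
resolution is attempted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file did not conform to its declared format; message names the spot."""


class ValidationError(ValueError):
    """Well-formed input with invalid content (negative time, bad label ...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale intensities.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene symbols, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite log2-scale intensities.
    class_labels : dict or None
        Optional map sample id -> "case" | "control".
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    class_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if self.class_labels is not None:
            bad = set(self.class_labels.values()) - {"case", "control"}
            if bad:
                raise ValidationError(f"class labels must be case/control, got {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset in the given order; unknown genes raise KeyError."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows], self.class_labels
        )

    def samples_in_class(self, label: str) -> list[str]:
        if self.class_labels is None:
            raise ValidationError("no class labels attached")
        return [s for s in self.sample_ids if self.class_labels.get(s) == label]


@dataclass
class GeneList:
    """An ordered, duplicate-free list of gene symbols with a free-text tag."""

    symbols: list[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        cleaned = [s.strip() for s in self.symbols]
        if any(not s for s in cleaned):
            raise ValidationError("empty gene symbol in list")
        seen: set[str] = set()
        ordered: list[str] = []
        for s in cleaned:
            if s not in seen:
                seen.add(s)
                ordered.append(s)
        self.symbols = ordered

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def as_set(self) -> set[str]:
        return set(self.symbols)


#: Binary contrasts used for the clinical covariates (reference level second).
AGE_LEVELS = (">=50", "<50")
STAGE_LEVELS = ("III-IV", "I-II")


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus dichotomized clinical covariates.

    ``time`` is study time (non-negative, unit left to the caller), ``event``
    is 1 for death/event and 0 for censoring. Categorical covariates are
    stored already collapsed to the contrasts used in the Cox models:
    age >=50 vs <50, female vs male, stage III-IV vs I-II, lymphatic
    invasion yes vs no (unknown -> NA).
    """

    data: pd.DataFrame  # index: sample ids

    REQUIRED = ("time", "event")
    OPTIONAL = ("age_group", "gender", "stage_group", "lymphatic_invasion")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if (df["time"] < 0).any():
            bad = df.index[df["time"] < 0][0]
            raise ValidationError(f"negative survival time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])][0]
            raise ValidationError(f"event must be 0/1; offending sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AnnotationSets:
    """term id -> gene set, with an optional explicit background universe."""

    sets: dict[str, set[str]]
    background: set[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.background is not None:
            for term, genes in self.sets.items():
                extra = genes - self.background
                if extra:
                    raise ValidationError(
                        f"term {term!r} contains genes outside the background: "
                        f"{sorted(extra)[:5]}"
                    )

    def effective_background(self) -> set[str]:
        if self.background is not None:
            return self.background
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    class_path: str | Path | None = None,
    linear_input: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV; optionally attach case/control labels.

    Duplicate gene rows (multiple probes per symbol) are collapsed by keeping
    the row with the highest mean intensity, with a warning. ``linear_input``
    applies log2(x+1) on load for matrices not already on the log scale.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: malformed expression TSV ({exc})") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids in header")

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()

    genes = [str(g).strip() for g in df.index]
    if len(set(genes)) != len(genes):
        frame = pd.DataFrame(values, index=genes)
        means = frame.mean(axis=1)
        keep_pos: dict[str, int] = {}
        for i, g in enumerate(genes):
            if g not in keep_pos or means.iloc[i] > means.iloc[keep_pos[g]]:
                keep_pos[g] = i
        dropped = len(genes) - len(keep_pos)
        warnings.warn(
            f"{path}: collapsed {dropped} duplicate gene rows by max mean intensity"
        )
        order = sorted(keep_pos.values())
        genes = [genes[i] for i in order]
        values = values[order]

    if linear_input:
        if (values < 0).any():
            raise ValidationError(f"{path}: negative values with linear_input=True")
        values = np.log2(values + 1.0)

    labels = None
    if class_path is not None:
        labels = _read_class_file(Path(class_path), set(str(c) for c in df.columns))
    return ExpressionMatrix(genes, [str(c) for c in df.columns], values, labels)


def _read_class_file(path: Path, sample_ids: set[str]) -> dict[str, str]:
    labels: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        sample, label = parts[0].strip(), parts[1].strip()
        if sample == "sample" and label == "label":  # optional header
            continue
        if label not in {"case", "control"}:
            raise ParseError(f"{path}:{lineno}: label must be case/control, got {label!r}")
        labels[sample] = label
    missing = sample_ids - set(labels)
    if missing:
        logger.info("%d samples without class labels", len(missing))
    return labels


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(Path(path), sep="\t", index_label="gene")


def write_class_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# gene lists and edge lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path, source_tag: str = "") -> GeneList:
    """One symbol per line; blank lines and '#' comments ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            symbols.append(s)
    return GeneList(symbols, source_tag=source_tag)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_edge_list(
    path: str | Path, dialect: Literal["sif", "tsv2"] = "sif"
) -> list[tuple[str, str]]:
    """Read an undirected interaction edge list.

    SIF lines are ``A <type> B [C ...]`` (one edge per target); tsv2 lines
    are ``A<TAB>B``. Edges are deduplicated as unordered pairs; self-pairs
    are dropped and their count logged. Returned pairs are canonically
    ordered (min, max) and sorted, so the result is invariant to line order
    and edge orientation in the file.
    """
    if dialect not in ("sif", "tsv2"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        tokens = raw.split("\t") if "\t" in raw else raw.split()
        tokens = [t.strip() for t in tokens if t.strip()]
        if dialect == "sif":
            if len(tokens) == 1:
                raise ParseError(f"{path}:{lineno}: SIF line with a lone node")
            if len(tokens) < 3:
                raise ParseError(f"{path}:{lineno}: expected 'source type target'")
            source, targets = tokens[0], tokens[2:]
        else:
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            source, targets = tokens[0], [tokens[1]]
        for target in targets:
            if source == target:
                self_loops += 1
                continue
            edges.add((min(source, target), max(source, target)))
    if self_loops:
        logger.info("%s: dropped %d self-interactions", path, self_loops)
    return sorted(edges)


def write_edge_list(
    edges: Iterable[tuple[str, str]],
    path: str | Path,
    dialect: Literal["sif", "tsv2"] = "sif",
    interaction_type: str = "pp",
) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            if dialect == "sif":
                fh.write(f"{a}\t{interaction_type}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

_GENDER_MAP = {"female": "female", "f": "female", "male": "male", "m": "male"}
_STAGE_GROUPS = {
    "i": "I-II", "ii": "I-II", "1": "I-II", "2": "I-II", "i-ii": "I-II",
    "iii": "III-IV", "iv": "III-IV", "3": "III-IV", "4": "III-IV",
    "iii-iv": "III-IV",
}
_INVASION_MAP = {"yes": "yes", "y": "yes", "1": "yes", "no": "no", "n": "no", "0": "no"}


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV and collapse covariates to their binary contrasts.

    Expected columns: sample, time, event, and optionally age, gender, stage,
    lymphatic_invasion. Age is dichotomized at 50 (>=50 vs <50), stage at
    III (III-IV vs I-II); unrecognized levels become missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")

    out = pd.DataFrame(index=pd.Index(df["sample"].str.strip(), name="sample"))
    out["time"] = pd.to_numeric(df["time"], errors="coerce").to_numpy()
    out["event"] = pd.to_numeric(df["event"], errors="coerce").to_numpy()
    if out["time"].isna().any() or out["event"].isna().any():
        raise ParseError(f"{path}: non-numeric time/event value")

    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce").to_numpy()
        out["age_group"] = np.where(
            np.isnan(age), None, np.where(age >= 50, AGE_LEVELS[0], AGE_LEVELS[1])
        )
    elif "age_group" in df.columns:
        out["age_group"] = [
            v if v in AGE_LEVELS else None
            for v in df["age_group"].str.strip().fillna("")
        ]
    if "gender" in df.columns:
        out["gender"] = [
            _GENDER_MAP.get(v) for v in df["gender"].str.strip().str.lower().fillna("")
        ]
    if "stage" in df.columns:
        out["stage_group"] = [
            _STAGE_GROUPS.get(v.removeprefix("stage").strip())
            for v in df["stage"].str.strip().str.lower().fillna("")
        ]
    elif "stage_group" in df.columns:
        out["stage_group"] = [
            v if v in STAGE_LEVELS else None
            for v in df["stage_group"].str.strip().fillna("")
        ]
    if "lymphatic_invasion" in df.columns:
        out["lymphatic_invasion"] = [
            _INVASION_MAP.get(v)
            for v in df["lymphatic_invasion"].str.strip().str.lower().fillna("")
        ]
    return ClinicalTable(out)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# GMT / subnetworks
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, background: set[str] | None = None) -> AnnotationSets:
    """Read annotation sets in GMT format (term, description, genes...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = [t.strip() for t in line.split("\t")]
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs term, desc, >=1 gene")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in sets:
            raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
        sets[term] = set(genes)
        descriptions[term] = desc
    return AnnotationSets(sets, background=background, descriptions=descriptions)


def write_gmt(sets: AnnotationSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.sets.items():
            desc = sets.descriptions.get(term, "")
            fh.write("\t".join([term, desc] + sorted(genes)) + "\n")


def write_subnetworks(subnets: Sequence, path: str | Path) -> None:
    """Write a subnetwork panel as GMT plus a JSON sidecar.

    One GMT line per subnetwork: id, description = comma-joined seed members,
    then member genes. The sidecar ``<path>.json`` records seed members and
    the up/down partition, which GMT cannot carry.
    """
    if not subnets:
        raise ValidationError("nothing to write: empty subnetwork list")
    path = Path(path)
    sidecar: dict[str, dict] = {}
    with open(path, "w") as fh:
        for sn in subnets:
            name = f"subnetwork_{sn.id}"
            desc = ",".join(sorted(sn.seed_members))
            fh.write("\t".join([name, desc] + sorted(sn.members)) + "\n")
            sidecar[name] = {
                "id": sn.id,
                "members": sorted(sn.members),
                "seed_members": sorted(sn.seed_members),
                "up_set": sorted(sn.up_set),
                "down_set": sorted(sn.down_set),
            }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_subnetworks(path: str | Path) -> list:
    """Inverse of :func:`write_subnetworks` (requires the JSON sidecar)."""
    from subnetmark.mcl import Subnetwork  # local import to avoid a cycle

    sidecar = json.loads(Path(str(path) + ".json").read_text())
    subnets = []
    for payload in sidecar.values():
        subnets.append(
            Subnetwork(
                id=payload["id"],
                members=set(payload["members"]),
                seed_members=set(payload["seed_members"]),
                up_set=set(payload["up_set"]),
                down_set=set(payload["down_set"]),
            )
        )
    subnets.sort(key=lambda sn: sn.id)
    return subnets
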