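"""Readers and writers for the external formats the pipeline consumes.

Variant tables and prediction tables are TSV with a header; multiple
sequence alignments are aligned FASTA with ``-`` as the gap character;
ontologies are OBO 1.2/1.4; amino acid property collections use the
AAindex flat-file format (sections 1, 2 and 3).

All protein positions are one-based coordinates on the ungapped human
reference sequence, matching substitution notation such as p.R97W.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

LABELS = ("pathogenic", "neutral")

PREDICTION_COLUMNS = (
    "variant_id",
    "mu",
    "sigma",
    "lower",
    "upper",
    "call",
    "combined",
)


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class VariantRecord:
    """One amino acid substitution, optionally labelled.

    ``position`` is one-based along the ungapped reference protein;
    ``ref_aa``/``var_aa`` are single-letter codes and must differ
    (synonymous records are rejected at parse time).
    """

    variant_id: str
    protein_id: str
    position: int
    ref_aa: str
    var_aa: str
    label: str | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for attr in ("ref_aa", "var_aa"):
            aa = getattr(self, attr)
            if aa not in _AA_SET:
                raise ValueError(f"{attr} {aa!r} is not a standard amino acid")
        if self.ref_aa == self.var_aa:
            raise ValueError(
                f"synonymous record {self.variant_id}: ref_aa == var_aa == {self.ref_aa}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS} or None, got {self.label!r}")


@dataclass
class Dataset:
    """An ordered, validated collection of variants.

    ``extras`` carries any optional numeric columns from the source table
    (externally computed omega, precomputed features, ...) indexed by
    variant_id.
    """

    records: list[VariantRecord]
    extras: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate variant_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {"pathogenic": 0, "neutral": 0, "unlabelled": 0}
        for r in self.records:
            counts[r.label if r.label is not None else "unlabelled"] += 1
        return counts

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            [r.label for r in self.records], index=self.variant_ids, name="label"
        )

    @property
    def family_ids(self) -> pd.Series:
        """Family id per variant; proteins without one become singleton families."""
        vals = [
            r.family_id if r.family_id is not None else f"__singleton__{r.protein_id}"
            for r in self.records
        ]
        return pd.Series(vals, index=self.variant_ids, name="family_id")

    def subset(self, variant_ids: Sequence[str]) -> "Dataset":
        wanted = set(variant_ids)
        recs = [r for r in self.records if r.variant_id in wanted]
        extras = (
            self.extras.loc[[r.variant_id for r in recs]]
            if not self.extras.empty
            else self.extras
        )
        return Dataset(records=recs, extras=extras)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "protein_id": [r.protein_id for r in self.records],
                "position": [r.position for r in self.records],
                "ref_aa": [r.ref_aa for r in self.records],
                "var_aa": [r.var_aa for r in self.records],
                "label": [r.label for r in self.records],
                "family_id": [r.family_id for r in self.records],
            }
        ).set_index("variant_id", drop=False)
        if not self.extras.empty:
            df = df.join(self.extras)
        return df


_MANDATORY = ("variant_id", "protein_id", "position", "ref_aa", "var_aa")
_OPTIONAL = ("label", "family_id")


def read_variants(path) -> Dataset:
    """Read a variant TSV into a validated :class:`Dataset`.

    The header must name variant_id, protein_id, position, ref_aa and
    var_aa; label, family_id and any numeric columns (e.g. omega) are
    optional and preserved in ``Dataset.extras``. Errors name the
    offending line number (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")

    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        row = row._asdict()
        try:
            position = int(row["position"])
        except ValueError:
            raise ParseError(f"{path}:{line}: non-integer position {row['position']!r}")
        label = row.get("label") or None
        family = row.get("family_id") or None
        try:
            rec = VariantRecord(
                variant_id=row["variant_id"],
                protein_id=row["protein_id"],
                position=position,
                ref_aa=row["ref_aa"],
                var_aa=row["var_aa"],
                label=label,
                family_id=family,
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from exc
        if rec.variant_id in seen:
            raise ParseError(f"{path}:{line}: duplicate variant_id {rec.variant_id!r}")
        seen.add(rec.variant_id)
        records.append(rec)

    extra_cols = [c for c in df.columns if c not in _MANDATORY + _OPTIONAL]
    extras = pd.DataFrame(index=pd.Index([r.variant_id for r in records], name="variant_id"))
    for col in extra_cols:
        extras[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce").to_numpy()
    return Dataset(records=records, extras=extras)


class ReferenceAlignment:
    """A protein MSA with a column map for one designated reference sequence.

    ``column_of(pos)`` maps a one-based ungapped reference position to the
    zero-based alignment column holding that residue. The map is strictly
    increasing, and composing it with ungapping of the reference row is
    the identity.
    """

    def __init__(self, alignment, reference_id: str):
        ids = [rec.id for rec in alignment]
        if reference_id not in ids:
            raise ParseError(f"reference sequence {reference_id!r} not in alignment")
        self.alignment = alignment
        self.reference_id = reference_id
        self._ref_row = str(alignment[ids.index(reference_id)].seq)
        self._map = [i for i, c in enumerate(self._ref_row) if c != "-"]

    @property
    def n_seq(self) -> int:
        return len(self.alignment)

    @property
    def reference_length(self) -> int:
        return len(self._map)

    def column_of(self, position: int) -> int:
        if not 1 <= position <= len(self._map):
            raise IndexError(
                f"position {position} outside reference length {len(self._map)}"
            )
        return self._map[position - 1]

    def column_residues(self, position: int) -> list[str]:
        col = self.column_of(position)
        return [str(rec.seq)[col] for rec in self.alignment]


def read_msa(path, reference_id: str) -> ReferenceAlignment:
    """Read an aligned FASTA and attach the reference column map.

    Raises :class:`ParseError` on ragged alignments or a missing
    reference id.
    """
    try:
        alignment = AlignIO.read(path, "fasta")
    except ValueError as exc:  # Biopython raises on ragged input
        raise ParseError(f"{path}: not a valid alignment ({exc})") from exc
    return ReferenceAlignment(alignment, reference_id)


class Ontology:
    """A DAG of ontology terms supporting ancestor closure queries.

    Edges follow the OBO convention (child -> parent). By default both
    ``is_a`` and ``part_of`` edges are traversed; pass
    ``relations=("is_a",)`` for is_a-only closure.
    """

    DEFAULT_RELATIONS = ("is_a", "part_of")

    def __init__(self, graph: nx.MultiDiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ParseError("ontology graph contains a cycle")
        self.graph = graph

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(
        self, term: str, relations: tuple[str, ...] = DEFAULT_RELATIONS
    ) -> set[str]:
        """All (transitive) ancestors of ``term``, excluding itself.

        Unknown terms yield an empty set (with a warning) rather than an
        error, so partially annotated inputs degrade gracefully.
        """
        if term not in self.graph:
            import warnings

            warnings.warn(f"unknown ontology term {term!r}; empty ancestor set")
            return set()
        sub = nx.MultiDiGraph(
            (u, v, k)
            for u, v, k in self.graph.edges(keys=True)
            if k in relations
        )
        if term not in sub:
            return set()
        return set(nx.descendants(sub, term))

    def closure(self, terms: Iterable[str], relations=DEFAULT_RELATIONS) -> set[str]:
        """Terms plus all their ancestors, deduplicated."""
        out: set[str] = set()
        for t in terms:
            if t in self.graph:
                out.add(t)
                out |= self.ancestors(t, relations=relations)
        return out


def read_obo(path) -> Ontology:
    """Parse an OBO 1.2/1.4 file into an :class:`Ontology`."""
    graph = obonet.read_obo(path)
    return Ontology(graph)


@dataclass
class AAIndexEntry:
    """One AAindex accession: either a 20-value profile or a 20x20 matrix."""

    accession: str
    description: str
    section: int
    values: dict[str, float] | None = None  # AAindex1
    matrix: pd.DataFrame | None = None  # AAindex2/3, row=ref, col=var

    @property
    def has_missing(self) -> bool:
        if self.values is not None:
            return any(math.isnan(v) for v in self.values.values())
        return bool(self.matrix.isna().to_numpy().any())


_AAINDEX1_ROW1 = "ARNDCQEGHI"
_AAINDEX1_ROW2 = "LKMFPSTWYV"


def _floats(tokens: list[str]) -> list[float]:
    return [math.nan if t in ("NA", "-", "NA.") else float(t) for t in tokens]


def read_aaindex(path, section: int) -> dict[str, AAIndexEntry]:
    """Parse an AAindex flat file (section 1, 2 or 3).

    AAindex1 ``I`` blocks become per-residue value maps; AAindex2/3 ``M``
    blocks become 20x20 matrices, symmetrized when stored
    lower-triangular. ``NA`` cells are kept as NaN and flagged via
    :attr:`AAIndexEntry.has_missing`.
    """
    if section not in (1, 2, 3):
        raise ValueError("section must be 1, 2 or 3")
    entries: dict[str, AAIndexEntry] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()

    i = 0
    accession = None
    description = ""
    while i < len(lines):
        line = lines[i]
        if line.startswith("H "):
            accession = line[2:].strip()
            description = ""
            i += 1
        elif line.startswith("D ") and accession:
            description = line[2:].strip()
            i += 1
        elif line.startswith("I ") and accession:
            if section != 1:
                raise ParseError(f"{accession}: 'I' block in AAindex{section} file")
            try:
                row1 = _floats(lines[i + 1].split())
                row2 = _floats(lines[i + 2].split())
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{accession}: truncated I block") from exc
            if len(row1) != 10 or len(row2) != 10:
                raise ParseError(f"{accession}: truncated I block")
            values = dict(zip(_AAINDEX1_ROW1, row1)) | dict(zip(_AAINDEX1_ROW2, row2))
            entries[accession] = AAIndexEntry(accession, description, 1, values=values)
            i += 3
        elif line.startswith("M ") and accession:
            if section == 1:
                raise ParseError(f"{accession}: 'M' block in AAindex1 file")
            spec = line[2:]
            fields = dict(
                part.strip().split(" = ")
                for part in spec.rstrip(",").split(",")
                if " = " in part
            )
            rows = fields.get("rows", "").strip()
            cols = fields.get("cols", "").strip()
            if not rows or not cols:
                raise ParseError(f"{accession}: malformed M header {spec!r}")
            data = np.full((len(rows), len(cols)), np.nan)
            j = i + 1
            for r in range(len(rows)):
                if j >= len(lines) or lines[j].startswith(("H ", "//")):
                    raise ParseError(f"{accession}: truncated M block")
                vals = _floats(lines[j].split())
                if len(vals) == len(cols):
                    data[r, :] = vals
                elif len(vals) == r + 1:  # lower-triangular
                    data[r, : r + 1] = vals
                else:
                    raise ParseError(f"{accession}: truncated M block at row {r + 1}")
                j += 1
            mat = pd.DataFrame(data, index=list(rows), columns=list(cols))
            if rows == cols:
                upper_missing = np.isnan(data[np.triu_indices(len(rows), k=1)]).all()
                if upper_missing and len(rows) > 1:
                    filled = np.where(np.isnan(data), data.T, data)
                    mat = pd.DataFrame(filled, index=list(rows), columns=list(cols))
            entries[accession] = AAIndexEntry(accession, description, section, matrix=mat)
            i = j
        else:
            i += 1
    return entries


def write_predictions(predictions: pd.DataFrame, path) -> None:
    """Write a prediction table as TSV with a deterministic column order.

    Floats are printed with 6 significant digits; re-reading the file
    recovers string/int fields exactly and floats to the printed
    precision.
    """
    missing = [c for c in PREDICTION_COLUMNS if c not in predictions.columns]
    if missing:
        raise ValueError(f"prediction table lacks column(s) {missing}")
    out = predictions.loc[:, list(PREDICTION_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_predictions(path) -> pd.DataFrame:
    """Read a prediction TSV written by :func:`write_predictions`."""
    df = pd.read_csv(path, sep="\t")
    if "combined" in df.columns:
        df["combined"] = df["combined"].astype(bool)
    return df
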