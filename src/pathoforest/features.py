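"""Per-variant feature engineering.

Four feature families feed the classifier:

* a Gene Ontology log-ratio score per protein (class-frequency contrast of
  ancestor-expanded GO terms),
* amino acid property deltas and substitution-matrix lookups from AAindex,
* a sequence profile from the ortholog MSA (reference/variant residue
  proportions and alignment depth),
* codon-level selective pressure omega (Ka/Ks), normally supplied as an
  input column; a clearly-labelled counting surrogate exists so the
  pipeline can run end to end without an external selection tool.

Missing values are represented as NaN in the assembled table and exposed
through an explicit mask — never silently imputed here.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import AAIndexEntry, Dataset, Ontology, ReferenceAlignment

DEFAULT_FEATURES = (
    "go_lr",
    "omega",
    "f_ref",
    "f_var",
    "n_seq",
    "KOSJ950114",
    "RACS820113",
    "TANS770104",
)


@dataclass
class GOFeatureContext:
    """Class-wise GO term frequencies estimated from training variants only.

    ``pathogenic_term_freq``/``neutral_term_freq`` count, for each
    ancestor-expanded term, how many training units of that class carry it
    (unit = variant by default; per-protein counting is available).
    """

    pathogenic_term_freq: Counter = field(default_factory=Counter)
    neutral_term_freq: Counter = field(default_factory=Counter)
    built_from: str = ""
    log_base: float | None = None  # None = natural log

    def _log(self, x: float) -> float:
        return math.log(x) if self.log_base is None else math.log(x, self.log_base)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "pathogenic_term_freq": dict(self.pathogenic_term_freq),
                    "neutral_term_freq": dict(self.neutral_term_freq),
                    "built_from": self.built_from,
                    "log_base": self.log_base,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GOFeatureContext":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pathogenic_term_freq=Counter(d["pathogenic_term_freq"]),
            neutral_term_freq=Counter(d["neutral_term_freq"]),
            built_from=d.get("built_from", ""),
            log_base=d.get("log_base"),
        )


def build_go_context(
    training: Dataset,
    annotations: Mapping[str, Iterable[str]],
    ontology: Ontology | None,
    counting: str = "variant",
    log_base: float | None = None,
) -> GOFeatureContext:
    """Build the class-frequency context for the GO log-ratio feature.

    Each protein's term set is ancestor-expanded through the ontology and
    deduplicated, so a term reachable along several paths counts once per
    protein. Under the default ``counting="variant"`` convention every
    training variant contributes its protein's deduplicated set to its
    class's frequency map (so the context reflects the class composition
    of the variant data); ``counting="protein"`` counts each protein once
    per class instead.
    """
    if len(training) == 0:
        raise ValueError("cannot build a GO context from an empty training set")
    if counting not in ("variant", "protein"):
        raise ValueError("counting must be 'variant' or 'protein'")

    expanded: dict[str, frozenset[str]] = {}
    for protein, terms in annotations.items():
        terms = set(terms)
        closed = ontology.closure(terms) | terms if ontology is not None else terms
        expanded[protein] = frozenset(closed)

    ctx = GOFeatureContext(log_base=log_base)
    seen_units: set[tuple[str, str]] = set()
    for rec in training:
        if rec.label is None:
            continue
        if counting == "protein":
            unit = (rec.protein_id, rec.label)
            if unit in seen_units:
                continue
            seen_units.add(unit)
        terms = expanded.get(rec.protein_id, frozenset())
        counter = (
            ctx.pathogenic_term_freq if rec.label == "pathogenic" else ctx.neutral_term_freq
        )
        counter.update(terms)

    fp = hashlib.sha1(
        ",".join(sorted(r.variant_id for r in training)).encode()
    ).hexdigest()[:12]
    ctx.built_from = fp
    return ctx


def go_log_ratio(protein_terms: Iterable[str], ctx: GOFeatureContext) -> float | None:
    """GO feature LR for one protein: sum of smoothed log frequency ratios.

    LR = sum_i log[(f(P_i)+1) / (f(N_i)+1)] over the protein's
    deduplicated (ancestor-expanded) term set; the +1 smoothing keeps every
    ratio finite. An empty term set yields ``None`` (feature missing).
    """
    terms = set(protein_terms)
    if not terms:
        return None
    return sum(
        ctx._log((ctx.pathogenic_term_freq[t] + 1) / (ctx.neutral_term_freq[t] + 1))
        for t in terms
    )


def aaindex1_delta(index: Mapping[str, float], ref_aa: str, var_aa: str) -> float | None:
    """Property difference index(ref) - index(var); ``None`` if either is absent/NaN."""
    ref = index.get(ref_aa)
    var = index.get(var_aa)
    if ref is None or var is None or math.isnan(ref) or math.isnan(var):
        return None
    return ref - var


def aaindex_matrix_value(matrix: pd.DataFrame, ref_aa: str, var_aa: str) -> float | None:
    """Substitution matrix lookup with row=reference, column=variant."""
    if ref_aa not in matrix.index or var_aa not in matrix.columns:
        return None
    val = matrix.at[ref_aa, var_aa]
    return None if pd.isna(val) else float(val)


def filter_complete_indices(
    entries: Mapping[str, AAIndexEntry],
) -> dict[str, AAIndexEntry]:
    """Drop every AAindex entry that contains any missing (NA) value."""
    return {acc: e for acc, e in entries.items() if not e.has_missing}


@dataclass(frozen=True)
class ConservationFeatures:
    """MSA-derived conservation descriptors for one variant position."""

    f_ref: float
    f_var: float
    n_seq: int
    omega: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_ref <= 1.0 and 0.0 <= self.f_var <= 1.0):
            raise ValueError("residue proportions must lie in [0, 1]")
        if self.f_ref + self.f_var > 1.0 + 1e-12:
            raise ValueError("f_ref + f_var cannot exceed 1")
        if self.n_seq < 1:
            raise ValueError("alignment must contain at least one sequence")
        if self.omega is not None and self.omega < 0:
            raise ValueError("omega is a rate ratio and cannot be negative")


def sequence_profile(
    alignment: ReferenceAlignment,
    ref_position: int,
    ref_aa: str,
    var_aa: str,
    count_gaps: bool = True,
) -> ConservationFeatures:
    """Reference/variant residue proportions at the variant's column.

    The denominator counts all aligned sequences by default, including
    rows gapped at that column (set ``count_gaps=False`` to restrict to
    residue-bearing rows). ``n_seq`` is always the full alignment depth.
    """
    residues = alignment.column_residues(ref_position)
    n_seq = len(residues)
    denom = n_seq if count_gaps else sum(1 for r in residues if r != "-")
    if denom == 0:
        return ConservationFeatures(f_ref=0.0, f_var=0.0, n_seq=n_seq)
    f_ref = sum(1 for r in residues if r == ref_aa) / denom
    f_var = sum(1 for r in residues if r == var_aa) / denom
    return ConservationFeatures(f_ref=f_ref, f_var=f_var, n_seq=n_seq)


_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE.get(codon)


def _syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous / non-synonymous site counts of one codon.

    Each of the three positions contributes 1/3 site per possible
    single-nucleotide change, classified by whether the encoded residue
    changes (changes to stop codons count as non-synonymous).
    """
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _translate(mutant) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _pairwise_diffs(ref: str, other: str) -> tuple[float, float]:
    """Average synonymous / non-synonymous difference counts between two codons.

    Multi-position differences are averaged over every mutational pathway
    (all orderings of the single-nucleotide steps), the standard counting
    treatment.
    """
    import itertools

    positions = [p for p in range(3) if ref[p] != other[p]]
    if not positions:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        current = ref
        syn = nonsyn = 0.0
        for pos in order:
            mutant = current[:pos] + other[pos] + current[pos + 1 :]
            if _translate(mutant) == _translate(current):
                syn += 1
            else:
                nonsyn += 1
            current = mutant
        syn_total += syn
        nonsyn_total += nonsyn
        n_paths += 1
    return syn_total / n_paths, nonsyn_total / n_paths


def surrogate_omega(
    codon_alignment: list[str], reference_codon_position: int
) -> float | None:
    """Counting-based stand-in for codon-level omega (Ka/Ks) at one codon.

    For the reference codon at ``reference_codon_position`` (one-based),
    pairwise synonymous and non-synonymous differences against every other
    sequence are counted (pathway-averaged), each total normalised by the
    reference codon's expected site counts. Returns the ratio of the
    non-synonymous to the synonymous rate, or ``None`` when the synonymous
    rate is zero (ratio undefined).

    This is a simple counting estimate, not a maximum-likelihood codon
    model; treat its values as qualitatively, not quantitatively,
    comparable to model-based omega.
    """
    if not codon_alignment:
        raise ValueError("empty codon alignment")
    lengths = {len(s) for s in codon_alignment}
    if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
        raise ValueError("codon alignment must be in frame with equal lengths")
    ref = codon_alignment[0]
    start = (reference_codon_position - 1) * 3
    if start + 3 > len(ref):
        raise IndexError(f"codon position {reference_codon_position} beyond alignment")
    ref_codon = ref[start : start + 3]
    if ref_codon in _STOPS:
        raise ValueError("internal stop codon in reference")

    syn_sites, nonsyn_sites = _syn_nonsyn_sites(ref_codon)
    syn_d = nonsyn_d = 0.0
    n_pairs = 0
    for other in codon_alignment[1:]:
        codon = other[start : start + 3]
        if "-" in codon or any(b not in _BASES for b in codon):
            continue
        s, n = _pairwise_diffs(ref_codon, codon)
        syn_d += s
        nonsyn_d += n
        n_pairs += 1
    if n_pairs == 0:
        return None
    syn_rate = syn_d / (syn_sites * n_pairs) if syn_sites > 0 else 0.0
    nonsyn_rate = nonsyn_d / (nonsyn_sites * n_pairs) if nonsyn_sites > 0 else 0.0
    if syn_rate == 0.0:
        return None
    return nonsyn_rate / syn_rate


@dataclass
class FeatureTable:
    """Variants x named numeric features with an explicit missingness mask."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature column names")

    @property
    def mask(self) -> pd.DataFrame:
        """True exactly where the value is absent."""
        return self.values.isna()

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path, sidecar: str | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="variant_id")
        if sidecar is not None:
            import json

            meta = {
                "features": self.feature_names,
                "missing_count": {
                    c: int(self.values[c].isna().sum()) for c in self.values.columns
                },
            }
            with open(sidecar, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t", index_col="variant_id"))


@dataclass
class FeatureBuilder:
    """Assembles the per-variant feature table from configured providers.

    Any provider may be absent; its cells are then masked (NaN), never
    zero-filled. Omega defaults to pass-through of an ``omega`` column on
    the dataset (model-based values computed externally); the counting
    surrogate is opt-in via ``omega_source="surrogate"`` and logged as
    non-equivalent to model-based estimates.
    """

    go_context: GOFeatureContext | None = None
    go_annotations: Mapping[str, Iterable[str]] | None = None
    ontology: Ontology | None = None
    alignments: Mapping[str, ReferenceAlignment] | None = None
    codon_alignments: Mapping[str, list[str]] | None = None
    aaindex1: Mapping[str, Mapping[str, float]] | None = None
    aaindex_matrices: Mapping[str, pd.DataFrame] | None = None
    omega_source: str = "input"
    count_gaps: bool = True

    def __post_init__(self) -> None:
        if self.omega_source not in ("input", "surrogate"):
            raise ValueError("omega_source must be 'input' or 'surrogate'")
        if self.omega_source == "surrogate":
            import logging

            logging.getLogger(__name__).warning(
                "using the counting omega surrogate: values are NOT equivalent "
                "to model-based selective-pressure estimates"
            )

    def _expanded_terms(self, protein_id: str) -> set[str]:
        if self.go_annotations is None:
            return set()
        terms = set(self.go_annotations.get(protein_id, ()))
        if not terms:
            return set()
        if self.ontology is not None:
            return self.ontology.closure(terms) | terms
        return terms

    def assemble(self, dataset: Dataset) -> FeatureTable:
        rows = []
        for rec in dataset:
            row: dict[str, float | None] = {}
            # GO log-ratio
            if self.go_context is not None:
                row["go_lr"] = go_log_ratio(
                    self._expanded_terms(rec.protein_id), self.go_context
                )
            else:
                row["go_lr"] = None
            # sequence profile
            aln = (self.alignments or {}).get(rec.protein_id)
            if aln is not None and rec.position <= aln.reference_length:
                prof = sequence_profile(
                    aln, rec.position, rec.ref_aa, rec.var_aa, self.count_gaps
                )
                row["f_ref"], row["f_var"], row["n_seq"] = (
                    prof.f_ref,
                    prof.f_var,
                    float(prof.n_seq),
                )
            else:
                row["f_ref"] = row["f_var"] = row["n_seq"] = None
            # selective pressure
            if self.omega_source == "input":
                val = (
                    dataset.extras.at[rec.variant_id, "omega"]
                    if "omega" in dataset.extras.columns
                    else None
                )
                row["omega"] = None if val is None or pd.isna(val) else float(val)
            else:
                codons = (self.codon_alignments or {}).get(rec.protein_id)
                row["omega"] = (
                    surrogate_omega(codons, rec.position) if codons else None
                )
            # amino acid properties
            for acc, index in (self.aaindex1 or {}).items():
                row[acc] = aaindex1_delta(index, rec.ref_aa, rec.var_aa)
            for acc, matrix in (self.aaindex_matrices or {}).items():
                row[acc] = aaindex_matrix_value(matrix, rec.ref_aa, rec.var_aa)
            rows.append(row)

        df = pd.DataFrame(rows, index=pd.Index(dataset.variant_ids, name="variant_id"))
        df = df.astype(float)
        return FeatureTable(df)
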