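"""Synthetic data with the statistical structure the classifier assumes.

The generator emulates a benchmark of amino acid substitutions in
protein-family-structured data: roughly balanced pathogenic/neutral
classes, per-protein class propensity (disease proteins vs. polymorphic
proteins), informative features drawn from class-conditional
distributions whose separability is a single ``overlap`` dial,
class-independent noise features, a right-skewed selective-pressure
variable with pathogenic mass near zero (variants at conserved sites),
GO-style term annotations with a class-skewed term pool, and annotation
sites placed so each type realises a configured pathogenic proportion.

Every generated quantity is recorded in a truth dictionary so recovery
experiments can score themselves.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import SiteAnnotation, write_sites
from .features import FeatureTable
from .io import AMINO_ACIDS, Dataset, Ontology, VariantRecord, read_obo


@dataclass(frozen=True)
class AnnotationTypeSpec:
    """One synthetic site type: its name, target Pa and variant coverage."""

    name: str
    pa: float
    density: float  # fraction of all variants overlapped by this type


DEFAULT_ANNOTATION_TYPES = (
    AnnotationTypeSpec("Binding", 0.90, 0.04),
    AnnotationTypeSpec("Metal", 0.92, 0.03),
    AnnotationTypeSpec("Active", 0.95, 0.03),
    AnnotationTypeSpec("IM", 0.88, 0.04),
    AnnotationTypeSpec("Site", 0.90, 0.03),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    ``overlap`` in [0, 1] controls class separability of the informative
    features: their class-conditional supports are unit-width uniforms
    shifted so that a fraction ``overlap`` of the supports coincide
    (0 = disjoint supports, 1 = identical distributions). The
    selective-pressure column is exponential with a pathogenic scale that
    interpolates toward the neutral scale as overlap grows.
    """

    n_proteins: int = 50
    protein_length: int = 120
    variants_per_protein: int = 8
    class_balance: float = 0.5
    protein_purity: float = 0.9  # P(variant label == its protein's propensity)
    informative_features: tuple[str, ...] = ("inf_1", "inf_2", "inf_3")
    n_noise_features: int = 5
    include_omega: bool = True
    overlap: float = 0.3
    family_sizes: tuple[int, ...] = (1, 1, 1, 1, 2, 2, 3, 5)  # heavy-tailed pool
    annotation_types: tuple[AnnotationTypeSpec, ...] = DEFAULT_ANNOTATION_TYPES
    go_signal: float = 0.8  # P(term drawn from the class-matched pool)
    go_terms_per_protein: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must lie in [0, 1]")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie strictly in (0, 1)")
        for t in self.annotation_types:
            if not (0.0 <= t.pa <= 1.0 and 0.0 <= t.density <= 1.0):
                raise ValueError(f"invalid annotation spec {t}")


@dataclass
class SyntheticData:
    """Everything the pipeline needs, plus ground truth."""

    dataset: Dataset
    features: FeatureTable
    sites: list[SiteAnnotation]
    go_annotations: dict[str, list[str]]
    ontology_text: str
    truth: dict = field(default_factory=dict)

    @property
    def ontology(self) -> Ontology:
        return read_obo(_io.StringIO(self.ontology_text))

    def write_bundle(self, outdir, msa_n_seq: int = 8) -> None:
        """Write the full input bundle (TSVs, OBO, MSAs, truth JSON)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        df = self.dataset.to_frame()
        df.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.features.to_tsv(out / "features.tsv", sidecar=out / "features.json")
        write_sites(self.sites, out / "sites.tsv")
        rows = [
            (p, t) for p, terms in self.go_annotations.items() for t in terms
        ]
        pd.DataFrame(rows, columns=["protein_id", "term_id"]).to_csv(
            out / "go_annotations.tsv", sep="\t", index=False
        )
        (out / "ontology.obo").write_text(self.ontology_text)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)
        msa_dir = out / "msa"
        msa_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(self.truth.get("seed", 0) + 12345)
        proteins = sorted({r.protein_id for r in self.dataset})
        length = self.truth.get("protein_length", 120)
        for p in proteins:
            profile = rng.uniform(0.5, 1.0, size=length)
            text = generate_toy_msa(
                msa_n_seq, length, profile, seed=int(rng.integers(2**31)),
                reference_id=f"{p}_ref",
            )
            (msa_dir / f"{p}.fasta").write_text(text)


def _draw_families(proteins: list[str], pool: tuple[int, ...], rng) -> dict[str, str]:
    """Assign proteins to families with sizes drawn from a heavy-tailed pool."""
    mapping: dict[str, str] = {}
    i = 0
    fam = 0
    while i < len(proteins):
        size = int(rng.choice(pool))
        fam += 1
        for p in proteins[i : i + size]:
            mapping[p] = f"F{fam:03d}"
        i += size
    return mapping


def generate_dataset(cfg: GeneratorConfig) -> SyntheticData:
    """Generate a labelled benchmark with planted signal.

    Informative feature i for class c is uniform on a unit interval:
    neutral on [0, 1], pathogenic on [1 - overlap, 2 - overlap]. Noise
    features are standard normal regardless of class. Selective pressure
    is exponential (neutral scale 0.8; pathogenic scale interpolates from
    0.12 at overlap 0 to 0.8 at overlap 1). Annotation sites of each
    configured type are single-residue intervals placed on sampled
    variants so the realised pathogenic proportion matches the requested
    Pa; infeasible requests (not enough variants of the needed class)
    raise.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    family_of = _draw_families(proteins, cfg.family_sizes, rng)
    propensity = {
        p: "pathogenic" if rng.random() < cfg.class_balance else "neutral"
        for p in proteins
    }

    aa = np.array(list(AMINO_ACIDS))
    records: list[VariantRecord] = []
    for p in proteins:
        positions = rng.choice(
            np.arange(1, cfg.protein_length + 1),
            size=min(cfg.variants_per_protein, cfg.protein_length),
            replace=False,
        )
        for pos in sorted(positions):
            ref, var = rng.choice(aa, size=2, replace=False)
            label = (
                propensity[p]
                if rng.random() < cfg.protein_purity
                else ("neutral" if propensity[p] == "pathogenic" else "pathogenic")
            )
            records.append(
                VariantRecord(
                    variant_id=f"{p}_{ref}{pos}{var}",
                    protein_id=p,
                    position=int(pos),
                    ref_aa=str(ref),
                    var_aa=str(var),
                    label=label,
                    family_id=family_of[p],
                )
            )
    if len({r.label for r in records}) < 2:
        raise ValueError("degenerate draw: only one class present; change the seed")

    n = len(records)
    is_path = np.array([r.label == "pathogenic" for r in records])

    cols: dict[str, np.ndarray] = {}
    shift = 1.0 - cfg.overlap
    for name in cfg.informative_features:
        base = rng.uniform(0.0, 1.0, size=n)
        cols[name] = base + shift * is_path
    if cfg.include_omega:
        neutral_scale = 0.8
        path_scale = 0.12 + (neutral_scale - 0.12) * cfg.overlap
        scales = np.where(is_path, path_scale, neutral_scale)
        cols["omega"] = rng.exponential(scales)
    for j in range(cfg.n_noise_features):
        cols[f"noise_{j + 1}"] = rng.normal(size=n)

    variant_ids = [r.variant_id for r in records]
    features = FeatureTable(
        pd.DataFrame(cols, index=pd.Index(variant_ids, name="variant_id"))
    )

    # annotation sites: single-residue intervals over sampled variants
    sites: list[SiteAnnotation] = []
    realized: dict[str, float] = {}
    unused = set(range(n))
    for spec in cfg.annotation_types:
        n_target = max(1, round(spec.density * n)) if spec.density > 0 else 0
        if n_target == 0:
            continue
        n_path_target = round(spec.pa * n_target)
        path_pool = [i for i in unused if is_path[i]]
        neut_pool = [i for i in unused if not is_path[i]]
        if n_path_target > len(path_pool) or (n_target - n_path_target) > len(neut_pool):
            raise ValueError(
                f"infeasible annotation spec {spec.name}: Pa={spec.pa} needs more "
                f"variants of one class than remain"
            )
        chosen = list(rng.choice(path_pool, size=n_path_target, replace=False)) + list(
            rng.choice(neut_pool, size=n_target - n_path_target, replace=False)
        )
        unused -= set(chosen)
        hits = 0
        for i in chosen:
            r = records[i]
            sites.append(SiteAnnotation(r.protein_id, r.position, r.position, spec.name))
            hits += int(is_path[i])
        realized[spec.name] = hits / n_target

    # GO annotations from a toy ontology with class-skewed leaf pools
    ontology_text = generate_toy_ontology(depth=3, branching=3)
    ont = read_obo(_io.StringIO(ontology_text))
    leaves = sorted(
        t for t in ont.graph.nodes if ont.graph.in_degree(t) == 0
    )
    half = len(leaves) // 2
    pools = {"pathogenic": leaves[:half], "neutral": leaves[half:]}
    go_annotations: dict[str, list[str]] = {}
    for p in proteins:
        own = propensity[p]
        other = "neutral" if own == "pathogenic" else "pathogenic"
        terms = set()
        for _ in range(cfg.go_terms_per_protein):
            pool = pools[own] if rng.random() < cfg.go_signal else pools[other]
            terms.add(str(rng.choice(pool)))
        go_annotations[p] = sorted(terms)

    truth = {
        "seed": cfg.seed,
        "overlap": cfg.overlap,
        "protein_length": cfg.protein_length,
        "informative_features": list(cfg.informative_features)
        + (["omega"] if cfg.include_omega else []),
        "noise_features": [f"noise_{j + 1}" for j in range(cfg.n_noise_features)],
        "realized_annotation_pa": realized,
        "protein_propensity": propensity,
        "leaf_pools": pools,
        "class_counts": {
            "pathogenic": int(is_path.sum()),
            "neutral": int(n - is_path.sum()),
        },
    }
    dataset = Dataset(records=records)
    if cfg.include_omega:
        dataset.extras = pd.DataFrame(
            {"omega": cols["omega"]}, index=pd.Index(variant_ids, name="variant_id")
        )
    return SyntheticData(
        dataset=dataset,
        features=features,
        sites=sites,
        go_annotations=go_annotations,
        ontology_text=ontology_text,
        truth=truth,
    )


def generate_toy_msa(
    n_seq: int,
    length: int,
    conservation_profile,
    seed: int = 0,
    reference_id: str = "ref",
) -> str:
    """FASTA text of an alignment whose per-column reference-residue
    frequency approximates ``conservation_profile``.

    Row 0 is the ungapped reference; every other row keeps the reference
    residue at column i with probability ``conservation_profile[i]`` and
    otherwise substitutes one of the 19 remaining residues.
    """
    profile = np.asarray(conservation_profile, dtype=float)
    if len(profile) != length:
        raise ValueError("profile length must equal alignment length")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    ref = rng.choice(aa, size=length)
    rows = [ref]
    for _ in range(n_seq - 1):
        keep = rng.random(length) < profile
        row = ref.copy()
        for i in np.flatnonzero(~keep):
            others = [a for a in AMINO_ACIDS if a != ref[i]]
            row[i] = rng.choice(others)
        rows.append(row)
    out = []
    for i, row in enumerate(rows):
        name = reference_id if i == 0 else f"seq{i}"
        out.append(f">{name}\n{''.join(row)}")
    return "\n".join(out) + "\n"


def generate_toy_ontology(depth: int, branching: int) -> str:
    """OBO text for a complete tree ontology of the given depth/branching.

    The root is ``T:0000001``; every non-root term has exactly one
    ``is_a`` parent, so a term at depth d has exactly d ancestors.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"T:{counter[0]:07d}"

    stanzas = []
    root = new_id()
    stanzas.append(f"[Term]\nid: {root}\nname: root")
    frontier = [root]
    for level in range(1, depth + 1):
        next_frontier = []
        for parent in frontier:
            for _ in range(branching):
                tid = new_id()
                stanzas.append(
                    f"[Term]\nid: {tid}\nname: level{level}\nis_a: {parent} ! parent"
                )
                next_frontier.append(tid)
        frontier = next_frontier
    return "format-version: 1.2\nontology: toy\n\n" + "\n\n".join(stanzas) + "\n"
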