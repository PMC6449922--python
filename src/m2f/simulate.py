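"""Synthetic pan-genome corpus generator.

Generates annotated prokaryotic genomes with the statistical structure the
downstream analysis assumes, with known truth:

* a multi-copy 16S rRNA array (controlled intra-genome divergence, optional
  N-stretch assembly artifacts, embedded 515f/926r primer sites so V4
  amplicon excision succeeds);
* five named single-copy housekeeping genes for MLSA concatenation;
* a protein-coding complement drawn from a core/accessory pan-genome.

Pairs of genomes are produced by evolving one ancestor along two independent
lineages for a given divergence time ``t``.  Two decoupled rates drive the
model: a per-site marker substitution rate (phylogenetic signal) and a
per-family accessory gain/loss rate (horizontal transfer / gene loss), so
the true shared-gene fraction and the expected marker identity of every pair
are known in closed form.  Substitutions are Jukes-Cantor-style uniform
replacements and markers never gain indels, which keeps the expected marker
identity analytic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import (
    AnnotatedGenome,
    GeneRecord,
    assemble_genome,
    rebuild_assembly,
    write_genome,
)

# --------------------------------------------------------------------------
# constants

PRIMER_515F = "GTGYCAGCMGCCGCGGTAA"
PRIMER_926R = "CCGYCAATTYMTTTRAGTTT"

RRNA_LENGTH = 1550
# canonical offsets: forward primer site, inter-primer (V4) region, reverse
# primer site (reverse complement of 926r) -- leaves 373 nt between primers
FWD_SITE_START = 514  # 0-based; site spans [514, 533)
REV_SITE_START = 906  # site spans [906, 926)

RRNA_PRODUCT = "16S ribosomal RNA"

#: the five single-copy housekeeping genes used for MLSA concatenation,
#: in canonical concatenation order, with CDS lengths (incl. stop codon)
MLSA_GENES = (
    ("rpsL", "30S ribosomal protein S12", 372),
    ("rpsO", "30S ribosomal protein S15", 267),
    ("der", "GTPase Der", 1320),
    ("atpH", "ATP synthase subunit delta", 534),
    ("pyrG", "CTP synthase", 1608),
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = np.array(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    )
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

ACCESSORY_PRODUCTS = (
    "IS5 family transposase",
    "type II toxin-antitoxin system toxin",
    "glycoside hydrolase family protein",
    "restriction endonuclease",
    "CRISPR-associated protein",
    "phage integrase",
    "ABC transporter permease",
    "hypothetical protein",
)

DEFAULT_CLASSES = (
    "Gammaproteobacteria",
    "Bacilli",
    "Clostridia",
    "Alphaproteobacteria",
    "Spirochaetia",
    "Cyanobacteria",
    "Mollicutes",
    "Flavobacteriia",
)

#: divergence strata used by the stock corpus: chosen with the default rates
#: so that expected marker identity spans roughly 100 down to 90 percent
DEFAULT_STRATA = (0.02, 0.1, 0.25, 0.5, 1.0)


# --------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class PanGenomeModel:
    """Parameters of the two-rate core/accessory pan-genome model.

    Rates are per unit divergence time: a genome pair at divergence ``t``
    has each marker site substituted with probability ``marker_sub_rate*t``
    per lineage and each accessory family gained/lost with probability
    ``gene_turnover_rate*t`` per lineage.  Core families are never lost.
    """

    n_core: int = 50
    n_accessory_pool: int = 100
    p_accessory: float = 0.4
    marker_sub_rate: float = 0.05
    gene_turnover_rate: float = 0.35
    gene_sub_rate: float = 0.0  # per-site CDS substitution per unit time
    rrna_copy_range: tuple[int, int] = (1, 4)
    intra_copy_divergence: float = 0.005
    n_artifact_prob: float = 0.0
    gene_length_range: tuple[int, int] = (300, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_accessory",
            "intra_copy_divergence",
            "n_artifact_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("marker_sub_rate", "gene_turnover_rate", "gene_sub_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_core < 1:
            raise ValueError("n_core must be >= 1")
        if self.n_accessory_pool < 0:
            raise ValueError("n_accessory_pool must be >= 0")
        lo, hi = self.rrna_copy_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("rrna_copy_range must lie within [1, 20]")
        lo, hi = self.gene_length_range
        if not (3 <= lo <= hi):
            raise ValueError("invalid gene_length_range")

    def replace(self, **kw) -> "PanGenomeModel":
        return dataclasses.replace(self, **kw)


@dataclass
class GenomePairTruth:
    """Ground truth for one evolved genome pair."""

    genome_id_a: str
    genome_id_b: str
    divergence_time: float
    true_shared_fraction: float
    expected_marker_identity: float


def expected_marker_identity(model: PanGenomeModel, divergence_time: float) -> float:
    """Expected percent identity between the two lineages' marker copies.

    Each lineage substitutes a site with probability ``q = rate * t``; under
    uniform replacement the per-site probability that the two lineages
    disagree is ``2q(1-q) + (2/3)q**2``.
    """
    q = model.marker_sub_rate * divergence_time
    if q > 1.0:
        raise ValueError("divergence so large that substitution probability > 1")
    d = 2.0 * q * (1.0 - q) + (2.0 / 3.0) * q * q
    return 100.0 * (1.0 - d)


# --------------------------------------------------------------------------
# sequence helpers


def _random_spacer(rng: np.random.Generator, lo: int = 20, hi: int = 100) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_BASES[rng.integers(0, 4, n)].tobytes().decode())


def random_nt(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def random_cds(rng: np.random.Generator, length_nt: int) -> str:
    """Random coding sequence: uniform non-stop codons, trailing TAA stop."""
    n_codons = length_nt // 3
    body = "".join(rng.choice(_NONSTOP_CODONS, n_codons - 1))
    return body + "TAA"


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        base if len(_IUPAC[base]) == 1 else _IUPAC[base][rng.integers(len(_IUPAC[base]))]
        for base in primer
    )


def mutate_nt(seq: str, q: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability q, uniformly to another base.

    Sites that are not plain ACGT (e.g. N) are left untouched.
    """
    if q <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr]
    mask = (rng.random(arr.size) < q) & (idx >= 0)
    hit = np.where(mask)[0]
    if hit.size == 0:
        return seq
    shift = rng.integers(1, 4, hit.size)
    arr[hit] = _BASES[(idx[hit] + shift) % 4]
    return arr.tobytes().decode()


#: 0-based [start, stop) spans of the embedded priming sites; held invariant
#: under mutation, emulating the conservation that makes 515f/926r universal
PROTECTED_RRNA_SPANS = (
    (FWD_SITE_START, FWD_SITE_START + len(PRIMER_515F)),
    (REV_SITE_START, REV_SITE_START + len(PRIMER_926R)),
)


def mutate_rrna(seq: str, q: float, rng: np.random.Generator) -> str:
    """16S mutation: uniform substitution with the priming sites restored."""
    mutated = mutate_nt(seq, q, rng)
    if mutated == seq:
        return seq
    out = list(mutated)
    for start, stop in PROTECTED_RRNA_SPANS:
        out[start:stop] = seq[start:stop]
    return "".join(out)


def mutate_cds(seq: str, q: float, rng: np.random.Generator) -> str:
    """Codon-safe substitution: mutated codons that become stops are repaired.

    A repaired site is re-substituted to another base that avoids the stop;
    if no alternative avoids it the substitution is reverted (rare).
    """
    if q <= 0.0:
        return seq
    mutated = mutate_nt(seq, q, rng)
    if mutated == seq:
        return seq
    out = list(mutated)
    # never let an internal codon become a stop
    for pos in range(0, len(out) - 3, 3):
        codon = "".join(out[pos : pos + 3])
        if codon not in _STOPS:
            continue
        orig = seq[pos : pos + 3]
        changed = [i for i in range(3) if codon[i] != orig[i]]
        fixed = False
        for i in rng.permutation(changed):
            for alt in rng.permutation([b for b in "ACGT" if b not in (codon[i], orig[i])]):
                trial = codon[:i] + alt + codon[i + 1 :]
                if trial not in _STOPS:
                    out[pos : pos + 3] = trial
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            out[pos : pos + 3] = orig
    return "".join(out)


# --------------------------------------------------------------------------
# gene ontology toy DAG

GO_ROOTS = {
    "molecular_function": "GO:0003674",
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
}

# (term, name, namespace, parents)
_GO_BASE: list[tuple[str, str, str, tuple[str, ...]]] = [
    ("GO:0003674", "molecular_function", "molecular_function", ()),
    ("GO:0005488", "binding", "molecular_function", ("GO:0003674",)),
    ("GO:0003824", "catalytic activity", "molecular_function", ("GO:0003674",)),
    ("GO:0016787", "hydrolase activity", "molecular_function", ("GO:0003824",)),
    ("GO:0003676", "nucleic acid binding", "molecular_function", ("GO:0005488",)),
    ("GO:0003723", "RNA binding", "molecular_function", ("GO:0003676",)),
    ("GO:0019843", "rRNA binding", "molecular_function", ("GO:0003723",)),
    ("GO:0046872", "metal ion binding", "molecular_function", ("GO:0005488",)),
    ("GO:0000287", "magnesium ion binding", "molecular_function", ("GO:0046872",)),
    ("GO:0005198", "structural molecule activity", "molecular_function", ("GO:0003674",)),
    ("GO:0003735", "structural constituent of ribosome", "molecular_function", ("GO:0005198",)),
    ("GO:0004803", "transposase activity", "molecular_function", ("GO:0003824",)),
    ("GO:0003964", "RNA-directed DNA polymerase activity", "molecular_function", ("GO:0003824",)),
    # diamond: site-specific deoxyribonuclease under hydrolase and nucleic acid binding
    ("GO:0009036", "type II site-specific deoxyribonuclease activity", "molecular_function",
     ("GO:0016787", "GO:0003676")),
    ("GO:0090729", "toxin activity", "molecular_function", ("GO:0003674",)),
    ("GO:0008150", "biological_process", "biological_process", ()),
    ("GO:0008152", "metabolic process", "biological_process", ("GO:0008150",)),
    ("GO:0006259", "DNA metabolic process", "biological_process", ("GO:0008152",)),
    ("GO:0006412", "translation", "biological_process", ("GO:0008152",)),
    ("GO:0006281", "DNA repair", "biological_process", ("GO:0006259",)),
    ("GO:0032196", "transposition", "biological_process", ("GO:0008150",)),
    ("GO:0006457", "protein folding", "biological_process", ("GO:0008150",)),
    ("GO:0071555", "cell wall organization", "biological_process", ("GO:0008150",)),
    ("GO:0009252", "peptidoglycan biosynthetic process", "biological_process", ("GO:0008152",)),
    ("GO:0008360", "regulation of cell shape", "biological_process", ("GO:0008150",)),
    ("GO:0006952", "defense response", "biological_process", ("GO:0008150",)),
    ("GO:0051607", "defense response to virus", "biological_process", ("GO:0006952",)),
    # diamond: CRISPR maintenance under defense response and DNA metabolic process
    ("GO:0043571", "maintenance of CRISPR repeat elements", "biological_process",
     ("GO:0006952", "GO:0006259")),
    ("GO:0045927", "positive regulation of growth", "biological_process", ("GO:0008150",)),
    ("GO:0005575", "cellular_component", "cellular_component", ()),
    ("GO:0005623", "cell", "cellular_component", ("GO:0005575",)),
    ("GO:0032991", "protein-containing complex", "cellular_component", ("GO:0005575",)),
    ("GO:0005737", "cytoplasm", "cellular_component", ("GO:0005623",)),
    ("GO:0005886", "plasma membrane", "cellular_component", ("GO:0005623",)),
    ("GO:0005840", "ribosome", "cellular_component", ("GO:0005737", "GO:0032991")),
    ("GO:0015934", "large ribosomal subunit", "cellular_component", ("GO:0005840",)),
    ("GO:0015935", "small ribosomal subunit", "cellular_component", ("GO:0005840",)),
    ("GO:0012506", "vesicle membrane", "cellular_component", ("GO:0005623",)),
    ("GO:0009341", "beta-galactosidase complex", "cellular_component", ("GO:0032991",)),
]

CORE_GO_POOL = (
    "GO:0006412", "GO:0019843", "GO:0003723", "GO:0046872", "GO:0003735",
    "GO:0006457", "GO:0006281", "GO:0071555", "GO:0005737", "GO:0005886",
    "GO:0015934", "GO:0015935", "GO:0000287", "GO:0008360", "GO:0009252",
)

ACCESSORY_GO_POOL = (
    "GO:0004803", "GO:0032196", "GO:0090729", "GO:0003964", "GO:0051607",
    "GO:0043571", "GO:0012506", "GO:0009341", "GO:0045927", "GO:0009036",
)

_FILLER_PARENTS = {
    "molecular_function": ("GO:0005488", "GO:0003824"),
    "biological_process": ("GO:0008152", "GO:0008150"),
    "cellular_component": ("GO:0005623", "GO:0032991"),
}


def toy_ontology(n_filler_per_namespace: int = 30):
    """Return (edges, names, namespaces) for the synthetic GO DAG.

    The DAG mixes a hand-built backbone of real GO identifiers (so outputs
    read naturally) with generic filler terms that broaden null-calibration
    tests.  It is entirely synthetic and carries no curated semantics.
    """
    edges: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for term, name, ns, parents in _GO_BASE:
        names[term] = name
        namespaces[term] = ns
        for p in parents:
            edges.append((term, p))
    counter = 9000001
    filler: list[str] = []
    for ns, parents in _FILLER_PARENTS.items():
        for i in range(n_filler_per_namespace):
            term = f"GO:{counter:07d}"
            counter += 1
            names[term] = f"synthetic {ns.replace('_', ' ')} term {i + 1}"
            namespaces[term] = ns
            edges.append((term, parents[i % len(parents)]))
            filler.append(term)
    return edges, names, namespaces, tuple(filler)


# --------------------------------------------------------------------------
# ancestor generation


def _family_products(rng: np.random.Generator, fam: str) -> str:
    if fam.startswith("core"):
        return f"conserved core protein {fam[4:]}"
    return str(rng.choice(ACCESSORY_PRODUCTS))


def _build_rrna_backbone(rng: np.random.Generator) -> str:
    seq = list(random_nt(rng, RRNA_LENGTH))
    fwd = _resolve_iupac(PRIMER_515F, rng)
    seq[FWD_SITE_START : FWD_SITE_START + len(fwd)] = fwd
    from .genomes import reverse_complement

    rev_site = reverse_complement(_resolve_iupac(PRIMER_926R, rng))
    seq[REV_SITE_START : REV_SITE_START + len(rev_site)] = rev_site
    return "".join(seq)


def generate_ancestor(
    model: PanGenomeModel,
    rng: np.random.Generator | None = None,
    genome_id: str = "ANC0000",
) -> AnnotatedGenome:
    """Generate one ancestral annotated genome under the model.

    The returned genome carries two extra attributes used by
    :func:`evolve_pair`: ``family_pool`` (family id -> (product, CDS) for
    every family in the accessory pool, present or not) and ``family_terms``
    (family id -> tuple of GO terms; populated by :func:`simulate_corpus`).
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng

    genes: list[GeneRecord] = []
    lo, hi = model.gene_length_range

    def _gene_length() -> int:
        n = int(rng.integers(lo, hi + 1))
        return max(6, n - n % 3)

    # core families
    for i in range(model.n_core):
        fam = f"core{i:04d}"
        genes.append(
            GeneRecord(
                gene_id="",
                feature_type="CDS",
                product=_family_products(rng, fam),
                contig="",
                start=0,
                end=0,
                strand="+",
                sequence=random_cds(rng, _gene_length()),
                family=fam,
            )
        )

    # the five MLSA housekeeping genes (core, single copy)
    for key, product, length in MLSA_GENES:
        genes.append(
            GeneRecord(
                gene_id="",
                feature_type="CDS",
                product=product,
                contig="",
                start=0,
                end=0,
                strand="+",
                sequence=random_cds(rng, length),
                family=f"mlsa:{key}",
            )
        )

    # accessory pool: generate every family once, sample presence
    family_pool: dict[str, tuple[str, str]] = {}
    for i in range(model.n_accessory_pool):
        fam = f"acc{i:04d}"
        family_pool[fam] = (_family_products(rng, fam), random_cds(rng, _gene_length()))
    present = rng.random(model.n_accessory_pool) < model.p_accessory
    for i, fam in enumerate(sorted(family_pool)):
        if present[i]:
            product, cds = family_pool[fam]
            genes.append(
                GeneRecord(
                    gene_id="",
                    feature_type="CDS",
                    product=product,
                    contig="",
                    start=0,
                    end=0,
                    strand="+",
                    sequence=cds,
                    family=fam,
                )
            )

    # 16S rRNA array with controlled intra-genome divergence
    backbone = _build_rrna_backbone(rng)
    lo_c, hi_c = model.rrna_copy_range
    n_copies = int(rng.integers(lo_c, hi_c + 1))
    for c in range(n_copies):
        seq = backbone if c == 0 else mutate_rrna(backbone, model.intra_copy_divergence, rng)
        genes.append(
            GeneRecord(
                gene_id="",
                feature_type="rRNA",
                product=RRNA_PRODUCT,
                contig="",
                start=0,
                end=0,
                strand="+",
                sequence=seq,
                family="rrna16S",
            )
        )

    rng.shuffle(genes)
    for i, g in enumerate(genes):
        g.gene_id = f"{genome_id}_g{i:04d}"
        g.strand = "+" if rng.random() < 0.5 else "-"
    spacers = [_random_spacer(rng) for _ in range(len(genes) + 1)]
    genome = assemble_genome(genome_id, genes, spacers)
    genome.family_pool = family_pool  # type: ignore[attr-defined]
    genome.family_terms = {}  # type: ignore[attr-defined]
    return genome


# --------------------------------------------------------------------------
# pair evolution


def _evolve_lineage(
    ancestor: AnnotatedGenome,
    model: PanGenomeModel,
    divergence_time: float,
    genome_id: str,
    rng: np.random.Generator,
) -> AnnotatedGenome:
    q_marker = model.marker_sub_rate * divergence_time
    q_gene = model.gene_sub_rate * divergence_time
    g_turn = model.gene_turnover_rate * divergence_time

    kept: list[GeneRecord] = []
    for gene in ancestor.genes:
        if gene.family.startswith("acc") and rng.random() < g_turn:
            continue  # accessory loss
        if gene.feature_type == "rRNA":
            seq = mutate_rrna(gene.sequence, q_marker, rng)
        elif gene.family.startswith("mlsa:"):
            seq = mutate_cds(gene.sequence, q_marker, rng)
        else:
            seq = mutate_cds(gene.sequence, q_gene, rng)
        kept.append(dataclasses.replace(gene, sequence=seq))

    # accessory gain: draw absent pool families, without replacement
    pool: dict[str, tuple[str, str]] = getattr(ancestor, "family_pool", {})
    present = {g.family for g in ancestor.genes}
    for fam in sorted(pool):
        if fam in present:
            continue
        if rng.random() < g_turn:
            product, cds = pool[fam]
            kept.append(
                GeneRecord(
                    gene_id="",
                    feature_type="CDS",
                    product=product,
                    contig="",
                    start=0,
                    end=0,
                    strand="+",
                    sequence=cds,
                    family=fam,
                )
            )

    for i, gene in enumerate(kept):
        gene.gene_id = f"{genome_id}_g{i:04d}"
        gene.strand = "+" if rng.random() < 0.5 else "-"
    spacers = [_random_spacer(rng) for _ in range(len(kept) + 1)]
    genome = assemble_genome(genome_id, kept, spacers, ancestor.taxonomy)
    genome.family_pool = pool  # type: ignore[attr-defined]
    genome.family_terms = getattr(ancestor, "family_terms", {})  # type: ignore[attr-defined]
    return genome


def coding_families(genome: AnnotatedGenome) -> list[str]:
    return [g.family for g in genome.genes if g.feature_type == "CDS"]


def true_shared_fraction(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome) -> float:
    """Shared coding-family fraction: 2|A & B| / (|A| + |B|).

    Computed directly from the generated family presence lists, never from
    sequence comparison.
    """
    fams_a = coding_families(genome_a)
    fams_b = coding_families(genome_b)
    shared = len(set(fams_a) & set(fams_b))
    return 2.0 * shared / (len(fams_a) + len(fams_b))


def evolve_pair(
    ancestor: AnnotatedGenome,
    model: PanGenomeModel,
    divergence_time: float,
    rng: np.random.Generator | None = None,
    ids: tuple[str, str] | None = None,
) -> tuple[AnnotatedGenome, AnnotatedGenome, GenomePairTruth]:
    """Evolve two descendants of ``ancestor`` for ``divergence_time`` each."""
    if divergence_time < 0:
        raise ValueError("divergence_time must be non-negative")
    emi = expected_marker_identity(model, divergence_time)  # validates rate*t
    if model.gene_turnover_rate * divergence_time > 1.0:
        raise ValueError("divergence so large that turnover probability > 1")
    if emi < 0.0:
        raise ValueError("divergence so large that expected identity < 0")
    rng = np.random.default_rng(model.seed + 1) if rng is None else rng
    id_a, id_b = ids if ids else (f"{ancestor.genome_id}A", f"{ancestor.genome_id}B")
    genome_a = _evolve_lineage(ancestor, model, divergence_time, id_a, rng)
    genome_b = _evolve_lineage(ancestor, model, divergence_time, id_b, rng)
    truth = GenomePairTruth(
        genome_id_a=id_a,
        genome_id_b=id_b,
        divergence_time=divergence_time,
        true_shared_fraction=true_shared_fraction(genome_a, genome_b),
        expected_marker_identity=emi,
    )
    return genome_a, genome_b, truth


def inject_artifacts(
    genome: AnnotatedGenome,
    model: PanGenomeModel,
    rng: np.random.Generator | None = None,
) -> AnnotatedGenome:
    """With probability ``n_artifact_prob`` per 16S copy, blank an internal
    window (>= 10 nt) with ``N`` -- emulating unresolved assembly stretches.
    At most one artifact per copy."""
    rrna = [g for g in genome.genes if g.feature_type == "rRNA"]
    if not rrna:
        raise ValueError("genome has no 16S copies")
    if model.n_artifact_prob <= 0.0:
        return genome
    rng = np.random.default_rng(model.seed + 2) if rng is None else rng
    changed = False
    for gene in genome.genes:
        if gene.feature_type != "rRNA":
            continue
        if rng.random() >= model.n_artifact_prob:
            continue
        n_len = int(rng.integers(10, 61))
        lo = 1
        hi = max(lo + 1, len(gene.sequence) - n_len - 1)
        start = int(rng.integers(lo, hi))
        gene.sequence = (
            gene.sequence[:start] + "N" * n_len + gene.sequence[start + n_len :]
        )
        changed = True
    if not changed:
        return genome
    rebuilt = rebuild_assembly(genome)
    rebuilt.family_pool = getattr(genome, "family_pool", {})  # type: ignore[attr-defined]
    rebuilt.family_terms = getattr(genome, "family_terms", {})  # type: ignore[attr-defined]
    return rebuilt


# --------------------------------------------------------------------------
# corpus


@dataclass
class SyntheticCorpus:
    """A set of evolved genome pairs plus the side tables the pipeline reads."""

    model: PanGenomeModel
    genomes: dict[str, AnnotatedGenome]
    pairs: list[GenomePairTruth]
    taxonomy: pd.DataFrame
    go_annotations: dict[str, tuple[str, ...]]  # protein id -> GO terms
    go_edges: list[tuple[str, str]]
    go_names: dict[str, str]
    go_namespaces: dict[str, str]

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_a": p.genome_id_a,
                    "genome_b": p.genome_id_b,
                    "divergence_time": p.divergence_time,
                    "true_shared_fraction": p.true_shared_fraction,
                    "expected_marker_identity": p.expected_marker_identity,
                }
                for p in self.pairs
            ]
        )

    def taxonomy_map(self, rank: str) -> dict[str, str]:
        return dict(zip(self.taxonomy["genome_id"], self.taxonomy[rank]))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in self.genomes.values():
            write_genome(genome, outdir)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        with open(outdir / "go_annotations.tsv", "w") as fh:
            for pid in sorted(self.go_annotations):
                terms = self.go_annotations[pid]
                if terms:
                    fh.write(f"{pid}\t{','.join(terms)}\n")
        with open(outdir / "go_isa.tsv", "w") as fh:
            for child, parent in self.go_edges:
                fh.write(f"{child}\t{parent}\n")


def _assign_family_terms(
    families: list[str],
    rng: np.random.Generator,
    filler: tuple[str, ...],
    go_null: bool,
    p_unannotated: float = 0.2,
) -> dict[str, tuple[str, ...]]:
    combined = CORE_GO_POOL + ACCESSORY_GO_POOL + filler
    out: dict[str, tuple[str, ...]] = {}
    for fam in families:
        if rng.random() < p_unannotated:
            out[fam] = ()
            continue
        if go_null:
            k = int(rng.integers(1, 4))
            terms = rng.choice(len(combined), size=min(k, len(combined)), replace=False)
            out[fam] = tuple(combined[i] for i in terms)
            continue
        pool = ACCESSORY_GO_POOL if fam.startswith("acc") else CORE_GO_POOL
        k = int(rng.integers(1, 3))
        picks = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        if rng.random() < 0.7:
            picks.append(filler[int(rng.integers(len(filler)))])
        out[fam] = tuple(dict.fromkeys(picks))
    return out


def simulate_corpus(
    model: PanGenomeModel,
    divergence_times: tuple[float, ...] = DEFAULT_STRATA,
    pairs_per_stratum: int = 3,
    go_null: bool = False,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> SyntheticCorpus:
    """Simulate a corpus of genome pairs across divergence strata.

    Each pair descends from its own ancestor (a star of independent pairs);
    both members share the pair's genus and class.  In ``go_null`` mode GO
    terms are attached to each gene occurrence independently of its
    core/accessory status, giving a calibration corpus with no true
    shared/unshared GO signal.
    """
    ss = np.random.SeedSequence(model.seed)
    n_pairs = len(divergence_times) * pairs_per_stratum
    children = ss.spawn(n_pairs)
    edges, names, namespaces, filler = toy_ontology()

    genomes: dict[str, AnnotatedGenome] = {}
    pairs: list[GenomePairTruth] = []
    tax_rows: list[dict[str, str]] = []
    go_annotations: dict[str, tuple[str, ...]] = {}

    pair_idx = 0
    for t in divergence_times:
        for _ in range(pairs_per_stratum):
            rng = np.random.default_rng(children[pair_idx])
            anc_id = f"P{pair_idx:04d}"
            ancestor = generate_ancestor(model, rng=rng, genome_id=anc_id)
            genome_a, genome_b, truth = evolve_pair(
                ancestor, model, t, rng=rng, ids=(f"{anc_id}A", f"{anc_id}B")
            )
            genome_a = inject_artifacts(genome_a, model, rng=rng)
            genome_b = inject_artifacts(genome_b, model, rng=rng)

            lineage = classes[pair_idx % len(classes)]
            genus = f"Genus{pair_idx:04d}"
            for genome in (genome_a, genome_b):
                genome.taxonomy = {
                    "domain": "Archaea" if lineage == "Archaea" else "Bacteria",
                    "phylum": f"Phylum_{lineage}",
                    "class": lineage,
                    "genus": genus,
                }
                tax_rows.append({"genome_id": genome.genome_id, **genome.taxonomy})
                genomes[genome.genome_id] = genome

            # GO terms ride gene families; in null mode they ride occurrences
            all_fams = sorted(
                {g.family for g in ancestor.genes if g.feature_type == "CDS"}
                | set(getattr(ancestor, "family_pool", {}))
            )
            fam_terms = _assign_family_terms(all_fams, rng, filler, go_null=False)
            for genome in (genome_a, genome_b):
                for gene in genome.genes:
                    if gene.feature_type != "CDS":
                        continue
                    if go_null:
                        one = _assign_family_terms(
                            [gene.family], rng, filler, go_null=True
                        )
                        go_annotations[gene.gene_id] = one[gene.family]
                    else:
                        go_annotations[gene.gene_id] = fam_terms.get(gene.family, ())

            pairs.append(truth)
            pair_idx += 1

    taxonomy = pd.DataFrame(tax_rows)
    return SyntheticCorpus(
        model=model,
        genomes=genomes,
        pairs=pairs,
        taxonomy=taxonomy,
        go_annotations=go_annotations,
        go_edges=edges,
        go_names=names,
        go_namespaces=namespaces,
    )
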