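"""Marker-gene extraction: 16S copies, V4 amplicons, MLSA concatenations.

16S genes are excised straight from the assembly using the GFF coordinates
(1-based inclusive; '-' strand features are reverse-complemented so every
record reads 5'->3').  Copies shorter than ``MIN_16S_LENGTH`` are dropped
and reported.  Copies carrying long N stretches, or aligning to a sibling
copy with a large gap fraction, are flagged as assembly artifacts and
excluded from copy statistics.

The V4 amplicon is located by in-silico PCR with the 515f/926r primer pair
under IUPAC degeneracy; by default the returned amplicon excludes the primer
sites themselves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .align import _get_nt_aligner, _trim_terminal_gaps, pairwise_identity
from .genomes import AnnotatedGenome, reverse_complement
from .simulate import PRIMER_515F, PRIMER_926R

MIN_16S_LENGTH = 1000
N_RUN_THRESHOLD = 10  # consecutive Ns that mark an assembly artifact
GAP_FRACTION_THRESHOLD = 0.20  # gap fraction vs sibling copy that flags

MLSA_ORDER = ("rpsL", "rpsO", "der", "atpH", "pyrG")

#: product-name table for the five MLSA housekeeping genes; matching is by
#: exact (case-insensitive) product string against these curated synonyms
MLSA_PRODUCT_SYNONYMS: dict[str, str] = {
    "30s ribosomal protein s12": "rpsL",
    "ribosomal protein s12": "rpsL",
    "30s ribosomal protein s15": "rpsO",
    "ribosomal protein s15": "rpsO",
    "gtpase der": "der",
    "gtp-binding protein der": "der",
    "ribosome biogenesis gtpase der": "der",
    "atp synthase subunit delta": "atpH",
    "atp-synthase delta": "atpH",
    "atp synthase delta chain": "atpH",
    "f0f1 atp synthase subunit delta": "atpH",
    "ctp synthase": "pyrG",
    "ctp synthetase": "pyrG",
}

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass
class MarkerRecord:
    """One extracted marker sequence tied to a genome."""

    genome_id: str
    marker_type: str  # "16S", "V4" or "MLSA"
    copy_index: int  # >= 1
    sequence: str
    source_coords: tuple[str, int, int, str] | None = None  # contig,start,end,strand
    flagged_artifact: bool = False

    @property
    def record_id(self) -> str:
        return f"{self.genome_id}|{self.marker_type}|{self.copy_index}"


@dataclass
class CopyStats:
    genome_id: str
    copy_number: int
    min_len: int | None
    max_len: int | None
    mean_len: float | None
    min_identity: float | None
    max_identity: float | None
    mean_identity: float | None
    n_flagged: int


@dataclass
class ExtractionReport:
    """Drops and exclusions accumulated while building marker datasets."""

    entries: list[dict] = field(default_factory=list)

    def add(self, genome_id: str, marker_type: str, reason: str, detail: str = "") -> None:
        self.entries.append(
            {
                "genome_id": genome_id,
                "marker_type": marker_type,
                "reason": reason,
                "detail": detail,
            }
        )


# ---------------------------------------------------------------------------
# 16S extraction


def extract_16s(
    genome: AnnotatedGenome,
    min_length: int = MIN_16S_LENGTH,
    report: ExtractionReport | None = None,
) -> list[MarkerRecord]:
    """One record per annotated 16S rRNA feature, in genomic order.

    Features whose product contains "16S ribosomal RNA" (case-insensitive)
    are excised from the assembly; records shorter than ``min_length`` are
    dropped and reported.
    """
    feats = [
        g
        for g in genome.genes
        if g.feature_type == "rRNA" and "16s ribosomal rna" in g.product.lower()
    ]
    feats.sort(key=lambda g: (g.contig, g.start))
    records: list[MarkerRecord] = []
    idx = 0
    for feat in feats:
        seq = genome.gene_sequence(feat)  # raises for unknown contig / bounds
        if len(seq) < min_length:
            if report is not None:
                report.add(
                    genome.genome_id,
                    "16S",
                    "below_min_length",
                    f"{feat.gene_id}:{len(seq)}nt",
                )
            continue
        idx += 1
        records.append(
            MarkerRecord(
                genome_id=genome.genome_id,
                marker_type="16S",
                copy_index=idx,
                sequence=seq,
                source_coords=(feat.contig, feat.start, feat.end, feat.strand),
            )
        )
    return records


def _longest_n_run(seq: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == "N" else 0
        best = max(best, run)
    return best


def _gap_fraction_vs(seq: str, ref: str) -> float:
    aln = _get_nt_aligner().align(seq, ref)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    lead, trail = _trim_terminal_gaps(row_a, row_b)
    columns = trail - lead
    if columns == 0:
        return 1.0
    gaps = row_a[lead:trail].count("-") + row_b[lead:trail].count("-")
    return gaps / columns


def flag_artifacts(
    record: MarkerRecord,
    all_copies: list[MarkerRecord],
    n_run: int = N_RUN_THRESHOLD,
    gap_fraction: float = GAP_FRACTION_THRESHOLD,
) -> bool:
    """True when the copy looks like an assembly artifact.

    Either it contains a run of >= ``n_run`` undetermined nucleotides, or a
    global alignment against the genome's most-common-length sibling copy
    has a gap fraction above ``gap_fraction``.
    """
    if _longest_n_run(record.sequence) >= n_run:
        return True
    siblings = [c for c in all_copies if c.record_id != record.record_id]
    if not siblings:
        return False
    lengths = [len(c.sequence) for c in siblings]
    mode_len = max(set(lengths), key=lambda L: (lengths.count(L), L))
    ref = next(c for c in siblings if len(c.sequence) == mode_len)
    return _gap_fraction_vs(record.sequence, ref.sequence) > gap_fraction


def apply_artifact_flags(records: list[MarkerRecord], **kw) -> list[MarkerRecord]:
    for rec in records:
        rec.flagged_artifact = flag_artifacts(rec, records, **kw)
    return records


def copy_statistics(records: list[MarkerRecord]) -> CopyStats:
    """Intra-genome 16S copy statistics over unflagged copies.

    Pairwise identities use the global-alignment identity kernel; artifact-
    flagged copies are excluded.  With a single clean copy the identity
    fields are undefined (None); if every copy is flagged, the length and
    identity fields are all None.
    """
    if not records:
        raise ValueError("no 16S records given")
    genome_id = records[0].genome_id
    clean = [r for r in records if not r.flagged_artifact]
    n_flagged = len(records) - len(clean)
    if not clean:
        return CopyStats(genome_id, len(records), None, None, None, None, None, None, n_flagged)
    lengths = sorted(len(r.sequence) for r in clean)
    idents: list[float] = []
    for a, b in itertools.combinations(sorted(clean, key=lambda r: r.record_id), 2):
        idents.append(pairwise_identity(a.sequence, b.sequence))
    return CopyStats(
        genome_id=genome_id,
        copy_number=len(records),
        min_len=lengths[0],
        max_len=lengths[-1],
        mean_len=sum(lengths) / len(lengths),
        min_identity=min(idents) if idents else None,
        max_identity=max(idents) if idents else None,
        mean_identity=sum(idents) / len(idents) if idents else None,
        n_flagged=n_flagged,
    )


# ---------------------------------------------------------------------------
# V4 in-silico PCR


def iupac_match_count(window: str, primer: str) -> int:
    """Number of window positions compatible with the (degenerate) primer.

    ``N`` in the subject matches nothing (an undetermined base cannot be
    confirmed to pair with the primer).
    """
    ok = 0
    for base, code in zip(window, primer):
        if base != "N" and base in IUPAC_SETS[code]:
            ok += 1
    return ok


def find_primer_site(
    seq: str, primer: str, start: int = 0, max_mismatches: int = 0
) -> int | None:
    """Leftmost 0-based offset >= start where the primer matches, else None."""
    plen = len(primer)
    need = plen - max_mismatches
    for i in range(start, len(seq) - plen + 1):
        if iupac_match_count(seq[i : i + plen], primer) >= need:
            return i
    return None


def extract_v4(
    record: MarkerRecord,
    fwd_primer: str = PRIMER_515F,
    rev_primer: str = PRIMER_926R,
    max_mismatches: int = 0,
    include_primers: bool = False,
) -> MarkerRecord | None:
    """In-silico PCR of the V4 region from a 16S record.

    The forward primer is matched on the record strand; the reverse primer
    as its reverse complement downstream of the forward site.  The first
    (leftmost) valid site pair wins.  Returns None when either primer is
    absent (the genome drops out of the V4 dataset).  By default the
    amplicon excludes both primer sequences.
    """
    if record.marker_type != "16S":
        raise ValueError("extract_v4 expects a 16S record")
    seq = record.sequence.upper()
    fwd_at = find_primer_site(seq, fwd_primer.upper(), 0, max_mismatches)
    if fwd_at is None:
        return None
    rev_site = reverse_complement(rev_primer.upper())
    rev_at = find_primer_site(seq, rev_site, fwd_at + len(fwd_primer), max_mismatches)
    if rev_at is None:
        return None
    if include_primers:
        amplicon = seq[fwd_at : rev_at + len(rev_site)]
    else:
        amplicon = seq[fwd_at + len(fwd_primer) : rev_at]
    if not amplicon:
        return None
    return MarkerRecord(
        genome_id=record.genome_id,
        marker_type="V4",
        copy_index=record.copy_index,
        sequence=amplicon,
        source_coords=record.source_coords,
        flagged_artifact=record.flagged_artifact,
    )


# ---------------------------------------------------------------------------
# MLSA concatenation


def build_mlsa(
    genome: AnnotatedGenome, report: ExtractionReport | None = None
) -> MarkerRecord | None:
    """Concatenate the five housekeeping genes in canonical order.

    Genes are matched by product name (curated synonym table).  Genomes
    missing any of the five, or carrying a duplicate, are excluded and
    reported -- exclusion is an expected outcome, not an error.
    """
    found: dict[str, list] = {key: [] for key in MLSA_ORDER}
    for gene in genome.genes:
        if gene.feature_type != "CDS":
            continue
        key = MLSA_PRODUCT_SYNONYMS.get(gene.product.strip().lower())
        if key is not None:
            found[key].append(gene)
    missing = [k for k, v in found.items() if not v]
    dupes = [k for k, v in found.items() if len(v) > 1]
    if missing or dupes:
        if report is not None:
            parts = []
            if missing:
                parts.append("missing:" + ",".join(missing))
            if dupes:
                parts.append("duplicated:" + ",".join(dupes))
            report.add(genome.genome_id, "MLSA", "excluded", ";".join(parts))
        return None
    seq = "".join(
        found[key][0].sequence or genome.gene_sequence(found[key][0])
        for key in MLSA_ORDER
    )
    return MarkerRecord(
        genome_id=genome.genome_id,
        marker_type="MLSA",
        copy_index=1,
        sequence=seq,
        source_coords=None,
    )


# ---------------------------------------------------------------------------
# dataset assembly


def build_marker_datasets(
    genomes: list[AnnotatedGenome],
    markers: tuple[str, ...] = ("16S", "V4", "MLSA"),
    min_16s_length: int = MIN_16S_LENGTH,
    primer_mismatches: int = 0,
    include_primers: bool = False,
) -> tuple[dict[str, list[MarkerRecord]], list[CopyStats], ExtractionReport]:
    """Extract every requested marker dataset from a genome collection."""
    report = ExtractionReport()
    datasets: dict[str, list[MarkerRecord]] = {m: [] for m in markers}
    stats: list[CopyStats] = []
    for genome in genomes:
        records = extract_16s(genome, min_length=min_16s_length, report=report)
        if records:
            apply_artifact_flags(records)
            stats.append(copy_statistics(records))
        if "16S" in datasets:
            datasets["16S"].extend(r for r in records if not r.flagged_artifact)
        if "V4" in datasets:
            got = False
            for rec in records:
                if rec.flagged_artifact:
                    continue
                v4 = extract_v4(
                    rec,
                    max_mismatches=primer_mismatches,
                    include_primers=include_primers,
                )
                if v4 is not None:
                    datasets["V4"].append(v4)
                    got = True
            if records and not got:
                report.add(genome.genome_id, "V4", "no_primer_hit")
        if "MLSA" in datasets:
            rec = build_mlsa(genome, report=report)
            if rec is not None:
                datasets["MLSA"].append(rec)
    return datasets, stats, report
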