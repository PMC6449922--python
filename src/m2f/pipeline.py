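"""End-to-end orchestration: simulate/load -> extract -> cluster -> shared ->
bins -> lineage -> GO, from a single YAML config.

Every run writes its resolved config next to its outputs and a
``manifest.tsv`` describing each stage.  All randomness flows from the
single config seed through ``numpy.random.SeedSequence`` spawning, so a
rerun with the same config and seed reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import binning, clustering, gostats, orthology, simulate
from . import markers as marker_extraction
from .genomes import AnnotatedGenome, load_genome

STAGES = ("extract", "cluster", "shared", "bins", "lineage", "go")


@dataclass
class RunConfig:
    genome_dir: str = ""
    output_dir: str = "m2f_out"
    markers: tuple[str, ...] = ("16S", "V4", "MLSA")
    thresholds: tuple[float, ...] = clustering.DEFAULT_THRESHOLDS
    mlsa_thresholds: tuple[float, ...] = clustering.MLSA_THRESHOLDS
    bin_marker: str = "V4"  # marker whose bins drive lineage/GO analyses
    analysis_bin: float = 99.0  # comparisons at this bin or higher
    min_16s_length: int = marker_extraction.MIN_16S_LENGTH
    primer_mismatches: int = 0
    include_primers: bool = False
    artifact_n_run: int = marker_extraction.N_RUN_THRESHOLD
    artifact_gap_fraction: float = marker_extraction.GAP_FRACTION_THRESHOLD
    shared_formula: str = "dual"
    score_floor: float = orthology.SCORE_FLOOR
    coverage_floor: float = orthology.COVERAGE_FLOOR
    go_alpha: float = 0.01
    go_propagate: bool = True
    lineage_alpha: float = 0.05
    make_plots: bool = False
    seed: int = 0
    # optional simulation block; when genome_dir is empty a corpus is
    # simulated with these settings and written under output_dir/corpus
    simulate: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("markers", "thresholds", "mlsa_thresholds"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("markers", "thresholds", "mlsa_thresholds"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _hash_strings(parts: list[str]) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\0")
    return h.hexdigest()[:12]


def load_corpus_dir(genome_dir: str | Path):
    """Load genomes plus side tables written by SyntheticCorpus.write()."""
    genome_dir = Path(genome_dir)
    genomes: dict[str, AnnotatedGenome] = {}
    tax_path = genome_dir / "taxonomy.tsv"
    taxonomy = (
        pd.read_csv(tax_path, sep="\t") if tax_path.exists() else pd.DataFrame()
    )
    tax_by_id = (
        {r["genome_id"]: dict(r) for _, r in taxonomy.iterrows()}
        if not taxonomy.empty
        else {}
    )
    for fna in sorted(genome_dir.glob("*.fna")):
        gid = fna.stem
        gff = genome_dir / f"{gid}.gff"
        if not gff.exists():
            raise FileNotFoundError(f"no GFF for genome {gid}")
        genomes[gid] = load_genome(gid, fna, gff, tax_by_id.get(gid))
    go_annotations = {}
    go_edges = []
    if (genome_dir / "go_annotations.tsv").exists():
        go_annotations = gostats.read_go_annotations(genome_dir / "go_annotations.tsv")
    if (genome_dir / "go_isa.tsv").exists():
        go_edges = gostats.read_isa_edges(genome_dir / "go_isa.tsv")
    truth_path = genome_dir / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    return genomes, taxonomy, go_annotations, go_edges, truth


def candidate_pairs(
    groups: list[clustering.ClusterGroup],
) -> list[tuple[str, str]]:
    """Unordered genome pairs co-clustering in at least one group."""
    pairs: set[tuple[str, str]] = set()
    for grp in groups:
        gs = sorted(grp.unique_genomes)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                pairs.add((gs[i], gs[j]))
    return sorted(pairs)


def write_marker_fasta(path: Path, records: list[marker_extraction.MarkerRecord]) -> None:
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: r.record_id):
            fh.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def clusters_frame(groups: list[clustering.ClusterGroup]) -> pd.DataFrame:
    rows = []
    for gi, grp in enumerate(groups):
        for member in grp.member_ids:
            rows.append(
                {
                    "group_id": gi,
                    "centroid": grp.centroid_id,
                    "member": member,
                    "member_identity_to_centroid": grp.member_identity[member],
                    "genome_id": member.split("|")[0],
                }
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> pd.DataFrame:
    """Execute the full workflow; returns the manifest table.

    Any stage failure raises with the stage name attached.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    manifest_rows: list[dict] = []

    def _record(stage: str, t0: float, outputs: list[str], inputs_hash: str) -> None:
        manifest_rows.append(
            {
                "stage": stage,
                "status": "complete",
                "input_hash": inputs_hash,
                "outputs": ";".join(outputs),
                "seconds": round(time.time() - t0, 2),
            }
        )

    stage = "setup"
    try:
        # ------------------------------------------------ corpus
        t0 = time.time()
        if config.genome_dir:
            genomes, taxonomy, go_annotations, go_edges, _truth = load_corpus_dir(
                config.genome_dir
            )
        else:
            stage = "simulate"
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            model_keys = {f.name for f in dataclasses.fields(simulate.PanGenomeModel)}
            model = simulate.PanGenomeModel(
                **{k: v for k, v in sim.items() if k in model_keys}
            )
            corpus = simulate.simulate_corpus(
                model,
                divergence_times=tuple(
                    sim.get("divergence_times", simulate.DEFAULT_STRATA)
                ),
                pairs_per_stratum=int(sim.get("pairs_per_stratum", 3)),
                go_null=bool(sim.get("go_null", False)),
            )
            corpus.write(outdir / "corpus")
            genomes = corpus.genomes
            taxonomy = corpus.taxonomy
            go_annotations = corpus.go_annotations
            go_edges = corpus.go_edges
            _record("simulate", t0, ["corpus"], _hash_strings(sorted(genomes)))
        genome_list = [genomes[g] for g in sorted(genomes)]

        # ------------------------------------------------ extract
        stage = "extract"
        t0 = time.time()
        datasets, copy_stats, report = marker_extraction.build_marker_datasets(
            genome_list,
            markers=config.markers,
            min_16s_length=config.min_16s_length,
            primer_mismatches=config.primer_mismatches,
            include_primers=config.include_primers,
        )
        outputs = []
        for mk, recs in datasets.items():
            path = outdir / f"{mk.lower()}.fasta"
            write_marker_fasta(path, recs)
            outputs.append(path.name)
        stats_df = pd.DataFrame([dataclasses.asdict(s) for s in copy_stats])
        stats_df.to_csv(outdir / "copy_stats.tsv", sep="\t", index=False)
        pd.DataFrame(report.entries).to_csv(
            outdir / "extraction_report.tsv", sep="\t", index=False
        )
        outputs += ["copy_stats.tsv", "extraction_report.tsv"]
        _record(stage, t0, outputs, _hash_strings(sorted(genomes)))

        # ------------------------------------------------ cluster
        stage = "cluster"
        t0 = time.time()
        runs: dict[str, dict[float, list[clustering.ClusterGroup]]] = {}
        genus_of = {g.genome_id: g.taxonomy.get("genus", "?") for g in genome_list}
        summary_rows = []
        outputs = []
        for mk, recs in datasets.items():
            ths = (
                config.mlsa_thresholds if mk == "MLSA" else config.thresholds
            )
            runs[mk] = clustering.cluster_at_thresholds(recs, ths)
            for t, groups in runs[mk].items():
                df = clusters_frame(groups)
                path = outdir / f"clusters_{mk.lower()}_{t:g}.tsv"
                df.to_csv(path, sep="\t", index=False)
                outputs.append(path.name)
                summ = clustering.summarize_clusters(groups, genus_of)
                summary_rows.append(
                    {
                        "marker": mk,
                        "threshold": t,
                        "n_groups": summ.n_groups,
                        "histogram": ";".join(
                            f"{k}:{v}" for k, v in summ.histogram.items()
                        ),
                        "genus_concordance": summ.genus_concordance,
                    }
                )
        pd.DataFrame(summary_rows).to_csv(
            outdir / "cluster_summary.tsv", sep="\t", index=False
        )
        outputs.append("cluster_summary.tsv")
        _record(stage, t0, outputs, _hash_strings([str(len(outputs))]))

        # ------------------------------------------------ shared gene content
        stage = "shared"
        t0 = time.time()
        bin_marker = config.bin_marker if config.bin_marker in runs else next(iter(runs))
        low_t = min(runs[bin_marker])
        pairs = candidate_pairs(runs[bin_marker][low_t])
        proteomes = {g.genome_id: g.proteins() for g in genome_list}
        comparisons = []
        for ga, gb in pairs:
            comparisons.append(
                orthology.rbh_match(
                    proteomes[ga],
                    proteomes[gb],
                    genome_a=ga,
                    genome_b=gb,
                    score_floor=config.score_floor,
                    coverage_floor=config.coverage_floor,
                    formula=config.shared_formula,
                )
            )
        shared_df = pd.DataFrame(
            {
                "genome_a": [c.genome_a for c in comparisons],
                "genome_b": [c.genome_b for c in comparisons],
                "n_genes_a": [c.n_genes_a for c in comparisons],
                "n_genes_b": [c.n_genes_b for c in comparisons],
                "matched": [len(c.matched_pairs) for c in comparisons],
                "percent_shared": [c.percent_shared for c in comparisons],
            }
        )
        shared_df.to_csv(outdir / "pairwise_shared.tsv", sep="\t", index=False)
        _record(stage, t0, ["pairwise_shared.tsv"], _hash_strings([str(len(pairs))]))

        # ------------------------------------------------ bins
        stage = "bins"
        t0 = time.time()
        outputs = []
        binned: dict[str, list[orthology.PairComparison]] = {}
        for mk in datasets:
            ths = config.mlsa_thresholds if mk == "MLSA" else config.thresholds
            retained, _excluded = binning.assign_bins(
                runs[mk], [dataclasses.replace(c) for c in comparisons], ths
            )
            binned[mk] = retained
            df = binning.bin_summary(retained, ths) if retained else pd.DataFrame()
            path = outdir / f"bin_summary_{mk.lower()}.tsv"
            df.to_csv(path, sep="\t", index=False)
            outputs.append(path.name)
            if config.make_plots and retained:
                from .plots import bin_boxplot

                bin_boxplot(retained, ths, outdir / f"bin_boxplot_{mk.lower()}.png")
        _record(stage, t0, outputs, _hash_strings([str(len(comparisons))]))

        # ------------------------------------------------ lineage
        stage = "lineage"
        t0 = time.time()
        class_of = {g.genome_id: g.taxonomy.get("class", "?") for g in genome_list}
        focal = [
            c
            for c in binned.get(bin_marker, [])
            if c.marker_bin is not None and c.marker_bin >= config.analysis_bin
        ]
        if focal and len({binning.label_lineages([c], class_of)[0] for c in focal}) >= 2:
            H, p_omni, lineage_results = binning.lineage_analysis(
                focal, class_of, alpha=config.lineage_alpha
            )
            lin_df = pd.DataFrame([dataclasses.asdict(r) for r in lineage_results])
            lin_df.insert(0, "kruskal_H", H)
            lin_df.insert(1, "kruskal_p", p_omni)
        else:
            lin_df = pd.DataFrame()
        lin_df.to_csv(outdir / "lineage_tests.tsv", sep="\t", index=False)
        _record(stage, t0, ["lineage_tests.tsv"], _hash_strings([str(len(focal))]))

        # ------------------------------------------------ GO enrichment
        stage = "go"
        t0 = time.time()
        if go_annotations and go_edges and focal:
            closure = gostats.annotate_and_propagate(
                go_annotations, go_edges, propagate=config.go_propagate
            )
            namespaces = gostats.namespace_map(go_edges)
            table = gostats.tally(focal, closure, namespaces)
            results = gostats.enrich(table, alpha=config.go_alpha)
            go_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        else:
            go_df = pd.DataFrame()
        go_df.to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)
        _record(stage, t0, ["go_enrichment.tsv"], _hash_strings([str(len(go_df))]))

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = pd.DataFrame(manifest_rows)
    # the manifest itself must be byte-stable across reruns: drop wall times
    stable = manifest.drop(columns=["seconds"])
    stable.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
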