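"""End-to-end pipeline orchestration and the subset-size benchmark.

Stage order: demultiplex → quality/length filter → optional random subset →
greedy clustering → cluster size gate → POA draft per cluster → RC-aware
merge → majority group selection → pileup polishing → primer trimming →
reference identification.  A hard error in any stage aborts that sample
only; other samples complete and the failure is summarised in the result.

Given identical input, configuration, and seed, every artifact the
pipeline writes is byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from . import consensus as cns
from . import demux as dmx
from .clustering import (
    ClusterConfig,
    assignment_table,
    cluster_table,
    gate_clusters,
    greedy_cluster,
)
from .read_qc import FilterConfig, RunStats, compute_stats, filter_reads, subset_reads
from .seq_io import ReferenceSequence, SequenceRead, write_fasta, write_fastq
from .species_id import IdentityReport, evaluate_criteria, identity_to_reference, trim_primers

__all__ = ["PipelineConfig", "SampleResult", "PipelineResult", "run_pipeline", "run_benchmark"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the workflow's standard defaults.

    Defaults: score-mode demultiplexing at min-score 99 (edit mode: 2 index
    / 11 primer edits), mean quality >= Q7, 321-521 bp length window, >10%
    cluster gate, 0.9 merge cutoff, 2 polishing rounds.
    """

    demux_mode: str = "score"
    min_score: float = 99.0
    max_index_edits: int = 2
    max_primer_edits: int = 11
    search_window: int = 150
    filter: FilterConfig = field(default_factory=FilterConfig)
    subset_size: Optional[int] = None
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    merge: cns.MergeConfig = field(default_factory=cns.MergeConfig)
    polish_rounds: int = 2
    poa_max_reads: int = 100
    expected_insert_length: int = 421
    length_tolerance: int = 5
    min_identity: float = 99.0
    min_read_fraction: float = 0.75
    seed: int = 42

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "PipelineConfig":
        path = Path(source)
        data = json.loads(path.read_text() if path.exists() else str(source))
        data["filter"] = FilterConfig(**data.get("filter", {}))
        data["cluster"] = ClusterConfig(**data.get("cluster", {}))
        data["merge"] = cns.MergeConfig(**data.get("merge", {}))
        return cls(**data)


@dataclass
class SampleResult:
    """Everything the pipeline produced (or failed to produce) for a sample."""

    sample_label: str
    ok: bool
    error: str = ""
    n_demultiplexed: int = 0
    n_filtered: int = 0
    n_clustered: int = 0
    majority_fraction: float = 0.0
    n_groups: int = 0
    draft_consensus: str = ""
    polished_consensus: str = ""
    trimmed_consensus: str = ""
    primer_flags: Dict[str, bool] = field(default_factory=dict)
    report: Optional[IdentityReport] = None
    stats: Optional[RunStats] = None
    clusters: Optional[pd.DataFrame] = None


@dataclass
class PipelineResult:
    samples: Dict[str, SampleResult]
    demux_log: List[dmx.DemuxAssignment]

    @property
    def all_passed(self) -> bool:
        return all(
            s.ok and s.report is not None and s.report.flags.get("identity_pass")
            for s in self.samples.values()
        )

    def report_table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples.values():
            row = {
                "sample_label": s.sample_label,
                "ok": s.ok,
                "error": s.error,
                "n_demultiplexed": s.n_demultiplexed,
                "n_filtered": s.n_filtered,
                "majority_fraction": s.majority_fraction,
            }
            if s.report is not None:
                row.update(
                    {
                        "best_reference": s.report.best_reference,
                        "percent_identity": s.report.percent_identity,
                        "matching_length": s.report.matching_length,
                        "consensus_length": s.report.consensus_length,
                        **{k: v for k, v in s.report.flags.items()},
                    }
                )
            rows.append(row)
        return pd.DataFrame(rows).sort_values("sample_label").reset_index(drop=True)


def _process_sample(
    label: str,
    reads: List[SequenceRead],
    primers: Tuple[str, str],
    references: Sequence[ReferenceSequence],
    cfg: PipelineConfig,
    outdir: Optional[Path],
) -> SampleResult:
    result = SampleResult(sample_label=label, ok=False, n_demultiplexed=len(reads))
    filtered, rejections = filter_reads(reads, cfg.filter)
    result.n_filtered = len(filtered)
    if not filtered:
        result.error = "no reads passed filtering"
        return result
    working = filtered
    if cfg.subset_size is not None:
        working = subset_reads(filtered, cfg.subset_size, seed=cfg.seed)
    total = len(working)

    clusters, unassigned = greedy_cluster(working, cfg.cluster)
    retained = gate_clusters(clusters, total, cfg.cluster.min_cluster_fraction)
    result.clusters = cluster_table(clusters)
    result.n_clustered = sum(c.size for c in retained)

    reads_by_id = {r.read_id: r for r in working}
    drafts = [
        (c, cns.cluster_consensus(c, reads_by_id, max_reads=cfg.poa_max_reads))
        for c in retained
    ]
    groups = cns.merge_rc_consensus(drafts, cfg.merge)
    majority, fraction = cns.select_majority(groups, total)
    result.n_groups = len(groups)
    result.majority_fraction = fraction

    draft = majority.lead_consensus()
    result.draft_consensus = draft
    support = [reads_by_id[rid] for rid in majority.read_ids]
    polished = cns.polish_consensus(draft, support, rounds=cfg.polish_rounds)
    result.polished_consensus = polished

    trim = trim_primers(polished, primers[0], primers[1], cfg.max_primer_edits)
    result.trimmed_consensus = trim.bases
    result.primer_flags = {
        "forward_primer_trimmed": trim.forward_trimmed,
        "reverse_primer_trimmed": trim.reverse_trimmed,
    }
    report = identity_to_reference(
        trim.bases, references, sample_label=label, fraction_reads_clustered=fraction
    )
    evaluate_criteria(
        report,
        min_identity=cfg.min_identity,
        expected_length=cfg.expected_insert_length,
        length_tolerance=cfg.length_tolerance,
        min_read_fraction=cfg.min_read_fraction,
    )
    result.report = report
    result.stats = compute_stats(
        {
            "demultiplexed": reads,
            "filtered": filtered,
            "clustering_input": working,
            "majority_group": support,
        }
    )
    result.ok = True

    if outdir is not None:
        sample_dir = outdir / label
        sample_dir.mkdir(parents=True, exist_ok=True)
        write_fastq(reads, sample_dir / "demultiplexed.fastq")
        write_fastq(filtered, sample_dir / "filtered.fastq")
        rejections.to_csv(sample_dir / "filter_rejections.tsv", sep="\t", index=False)
        assignment_table(clusters).to_csv(
            sample_dir / "cluster_assignments.tsv", sep="\t", index=False
        )
        result.clusters.to_csv(sample_dir / "clusters.tsv", sep="\t", index=False)
        write_fasta(
            [
                ReferenceSequence(f"{label}_consensus", trim.bases),
            ],
            sample_dir / "consensus.fasta",
        )
        summary = {
            "sample_label": label,
            "n_demultiplexed": result.n_demultiplexed,
            "n_filtered": result.n_filtered,
            "n_clustering_input": total,
            "majority_fraction": fraction,
            "percent_identity": report.percent_identity,
            "matching_length": report.matching_length,
            "flags": report.flags,
            "primer_flags": result.primer_flags,
        }
        (sample_dir / "report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return result


def run_pipeline(
    reads: Sequence[SequenceRead],
    panel: Sequence[dmx.IndexPair],
    primers: Tuple[str, str],
    references: Sequence[ReferenceSequence],
    cfg: Optional[PipelineConfig] = None,
    output_dir: Union[str, Path, None] = None,
) -> PipelineResult:
    """Run the full pipeline; per-sample errors do not abort the run."""
    cfg = cfg or PipelineConfig()
    outdir = Path(output_dir) if output_dir is not None else None
    by_sample, log = dmx.demux_reads(
        reads,
        panel,
        mode=cfg.demux_mode,
        primers=primers,
        min_score=cfg.min_score,
        max_index_edits=cfg.max_index_edits,
        max_primer_edits=cfg.max_primer_edits,
        search_window=cfg.search_window,
    )
    results: Dict[str, SampleResult] = {}
    for label in sorted(by_sample):
        sample_reads = by_sample[label]
        if not sample_reads:
            continue  # no reads demultiplexed to this panel entry
        try:
            results[label] = _process_sample(
                label, sample_reads, primers, references, cfg, outdir
            )
        except Exception as exc:  # fault isolation between samples
            logger.exception("sample %s failed", label)
            results[label] = SampleResult(
                sample_label=label,
                ok=False,
                error=f"{type(exc).__name__}: {exc}",
                n_demultiplexed=len(sample_reads),
            )
    pipeline_result = PipelineResult(samples=results, demux_log=log)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        dmx.summarize_demux(log).to_csv(
            outdir / "demux_summary.tsv", sep="\t", index=False
        )
        pipeline_result.report_table().to_csv(
            outdir / "reports.tsv", sep="\t", index=False
        )
        cfg.to_json(outdir / "config.json")
    for label, res in results.items():
        logger.info(
            "%s: demux=%d filtered=%d majority=%.1f%% ok=%s",
            label,
            res.n_demultiplexed,
            res.n_filtered,
            100 * res.majority_fraction,
            res.ok,
        )
    return pipeline_result


def run_benchmark(
    reads: Sequence[SequenceRead],
    panel: Sequence[dmx.IndexPair],
    primers: Tuple[str, str],
    references: Sequence[ReferenceSequence],
    cfg: Optional[PipelineConfig] = None,
    subset_sizes: Sequence[int] = (100, 500, 5000),
    modes: Sequence[str] = ("score", "edit"),
) -> pd.DataFrame:
    """Pipeline over the subset-size × demux-mode grid; one row per cell/sample.

    Columns report identity, matching length, and clustered-read counts and
    fractions, plus per-(mode, subset) means and standard deviations across
    samples.  An empty grid yields an empty table.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for mode in modes:
        for k in subset_sizes:
            sub_cfg = dataclasses.replace(cfg, demux_mode=mode, subset_size=k)
            result = run_pipeline(reads, panel, primers, references, sub_cfg)
            for label, s in result.samples.items():
                row = {
                    "demux_mode": mode,
                    "subset_size": k,
                    "sample_label": label,
                    "ok": s.ok,
                    "n_filtered": s.n_filtered,
                    "n_clustered_reads": s.n_clustered,
                    "majority_fraction": s.majority_fraction,
                    "percent_identity": (
                        s.report.percent_identity if s.report else float("nan")
                    ),
                    "matching_length": (
                        s.report.matching_length if s.report else 0
                    ),
                }
                rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    aggregates = (
        table[table["ok"]]
        .groupby(["demux_mode", "subset_size"])
        .agg(
            mean_identity=("percent_identity", "mean"),
            sd_identity=("percent_identity", "std"),
            mean_matching_length=("matching_length", "mean"),
            mean_majority_fraction=("majority_fraction", "mean"),
        )
        .reset_index()
    )
    return table.merge(aggregates, on=["demux_mode", "subset_size"], how="left")
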