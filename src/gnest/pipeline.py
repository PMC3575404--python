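"""End-to-end orchestration: inputs -> scored genome -> report files."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from datetime import datetime, timezone
from typing import Optional, Sequence

from . import __version__
from .correlation import correlation_by_chromosome
from .data_model import ExpressionMatrix, GeneRecord, SyntenyBlockSet
from .null_model import benjamini_hochberg, empirical_pvalues
from .preprocess import SilentPolicy, flag_silent_genes, remove_overlapping_transcripts
from .scoring import (
    ScoredGenome,
    set_total_scores,
    write_custom_track,
    write_report,
    write_tns_matrix,
)
from .synteny import set_synteny_scores
from .windows import WindowSpec, compute_all_ancs, enumerate_windows


@dataclasses.dataclass
class PipelineParams:
    window_spec: WindowSpec = WindowSpec()
    silent_policy: Optional[SilentPolicy] = None
    n_shuffles: int = 10
    seed: int = 0
    alpha: float = 0.05
    pseudo_count: bool = False
    no_synteny: bool = False  # expression-only mode: SS fixed at 1 for all windows


def run_pipeline(
    genes: Sequence[GeneRecord],
    expr: ExpressionMatrix,
    block_sets: Sequence[SyntenyBlockSet],
    params: PipelineParams = PipelineParams(),
) -> ScoredGenome:
    """Preprocess, enumerate, correlate, permute, conserve, score.

    ``no_synteny`` runs an expression-only variant in which every window
    gets SS = 1 (so TNS reduces to the significance-gated ANC); this is an
    extension for users without comparison-species block data, not part of
    the published scoring scheme.
    """
    nonredundant = remove_overlapping_transcripts(list(genes), expr)
    silent = flag_silent_genes(expr, params.silent_policy)
    windows = enumerate_windows(nonredundant, params.window_spec)
    corr = correlation_by_chromosome(expr, nonredundant, silent)
    compute_all_ancs(windows, corr)
    empirical_pvalues(
        windows,
        expr,
        nonredundant,
        silent,
        n_shuffles=params.n_shuffles,
        seed=params.seed,
        pseudo_count=params.pseudo_count,
    )
    if params.no_synteny:
        for w in windows:
            w.ss = 1.0
    else:
        if not block_sets:
            raise ValueError(
                "no synteny block sets provided; pass --no-synteny for "
                "expression-only scoring"
            )
        set_synteny_scores(windows, block_sets)
    set_total_scores(windows, params.alpha)
    return ScoredGenome(neighborhoods=windows, genes=list(nonredundant), alpha=params.alpha)


def write_outputs(
    scored: ScoredGenome,
    out_dir: str,
    params: PipelineParams,
    input_paths: Optional[dict[str, str]] = None,
    report_bh: bool = False,
) -> dict[str, str]:
    """Write report TSV, bedGraph track, TNS matrix, and a run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "report": os.path.join(out_dir, "neighborhoods.tsv"),
        "track": os.path.join(out_dir, "best_tns.bedGraph"),
        "matrix": os.path.join(out_dir, "tns_matrix.tsv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_report(scored, paths["report"])
    write_custom_track(scored, paths["track"])
    write_tns_matrix(scored, paths["matrix"])
    if report_bh:
        paths["bh"] = os.path.join(out_dir, "neighborhoods_bh.tsv")
        _write_bh(scored, paths["bh"])
    _write_manifest(paths["manifest"], params, input_paths or {})
    return paths


def _write_bh(scored: ScoredGenome, path: str) -> None:
    rows = sorted(
        scored.neighborhoods,
        key=lambda w: (w.chrom, w.span_start, w.size_genes, w.member_gene_ids),
    )
    adj = benjamini_hochberg([w.p_value for w in rows])
    with open(path, "w") as fh:
        fh.write("chrom\tspan_start\tspan_end\tsize\tp_value\tp_bh\n")
        for w, q in zip(rows, adj):
            fh.write(
                f"{w.chrom}\t{w.span_start}\t{w.span_end}\t{w.size_genes}\t"
                f"{w.p_value:.6g}\t{q:.6g}\n"
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(path: str, params: PipelineParams, input_paths: dict[str, str]) -> None:
    manifest = {
        "tool_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": params.seed,
        "n_shuffles": params.n_shuffles,
        "alpha": params.alpha,
        "pseudo_count": params.pseudo_count,
        "no_synteny": params.no_synteny,
        "window_spec": dataclasses.asdict(params.window_spec),
        "silent_policy": (
            dataclasses.asdict(params.silent_policy) if params.silent_policy else None
        ),
        "inputs": {
            name: {"path": p, "sha256": _sha256(p)}
            for name, p in input_paths.items()
            if p and os.path.exists(p)
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
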