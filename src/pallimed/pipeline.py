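"""End-to-end orchestration: files in, tables/networks/report out.

``run_pipeline`` chains the stages — lexicon loading, note
extraction into the document-term matrix, the median cohort split,
group frequencies, the trigger index, and per-group thresholded
co-occurrence networks — and writes every artifact plus a
machine-readable run report. Any stage failure aborts with the stage
name attached. Output is byte-stable: rerunning on the same inputs
and config produces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .cohort import EARLY, LATE, read_cohort, split_by_median
from .extract import build_dtm, read_notes, write_dtm
from .lexicon import default_lexicon_path, load_lexicon
from .network import (
    build_network,
    cocorrelation,
    export_network,
    top_cooccurrences,
)
from .trigger import compute_pti, group_frequencies, write_trigger_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("pallimed")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one analysis run.

    Defaults encode the reference analysis: binary matrix, phi
    co-correlation with edge threshold 0.5, node frequency cut-offs
    3 (early group) and 2 (late group), ">= median" early rule with
    the lower-median convention.
    """

    notes_path: Union[str, Path]
    cohort_path: Union[str, Path]
    output_dir: Union[str, Path]
    lexicon_path: Optional[Union[str, Path]] = None
    dtm_mode: str = "binary"
    correlation_method: str = "phi"
    min_frequency_early: int = 3
    min_frequency_late: int = 2
    corr_threshold: float = 0.5
    median_rule: str = "lower"
    normalize_pti: bool = False
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_frequency_early < 0 or self.min_frequency_late < 0:
            raise ValueError("min_frequency thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("notes_path", "cohort_path", "output_dir", "lexicon_path"):
            if out[key] is not None:
                out[key] = str(out[key])
        return out

    def fingerprint(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts.

    Returns the run report (also written as ``report.json``):
    config echo and fingerprint, group sizes and threshold, the
    top-k trigger table, and the top-k co-occurrences per group.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("pallimed %s", __version__)
        logger.info("config %s", json.dumps(cfg.to_dict(), sort_keys=True))

        lexicon_path = cfg.lexicon_path or default_lexicon_path()
        lexicon = _stage("lexicon")(load_lexicon)(lexicon_path)
        logger.info("lexicon: %d canonical terms", len(lexicon))

        docs = _stage("extraction")(read_notes)(cfg.notes_path)
        if not docs:
            raise PipelineError("extraction", f"no notes in {cfg.notes_path}")
        dtm = _stage("extraction")(build_dtm)(docs, lexicon, mode=cfg.dtm_mode)
        write_dtm(dtm, out_dir / "dtm.tsv")
        logger.info("matrix: %d patients x %d terms", *dtm.shape)

        records = _stage("cohort")(read_cohort)(cfg.cohort_path)
        groups = _stage("cohort")(split_by_median)(records, rule=cfg.median_rule)
        logger.info(
            "split: threshold %s days, %d early / %d late",
            groups.threshold_days, groups.n_early, groups.n_late,
        )

        freqs = _stage("trigger_index")(group_frequencies)(dtm, groups)
        table = _stage("trigger_index")(compute_pti)(
            freqs,
            normalize=cfg.normalize_pti,
            group_sizes=(groups.n_early, groups.n_late),
        )
        write_trigger_table(table, out_dir / "trigger_table.tsv")

        report_networks = {}
        for group, min_freq in (
            (EARLY, cfg.min_frequency_early),
            (LATE, cfg.min_frequency_late),
        ):
            sub = dtm.subset_rows(
                [p for p in dtm.row_ids if groups.group_of(p) == group]
            )
            if sub.shape[1] == 0:
                logger.warning("group %s has no observed terms", group)
                report_networks[group] = {"nodes": 0, "edges": 0, "top": []}
                continue
            corr = _stage("network")(cocorrelation)(sub, method=cfg.correlation_method)
            net = _stage("network")(build_network)(
                sub, corr=corr, min_frequency=min_freq,
                corr_threshold=cfg.corr_threshold,
            )
            export_network(net, out_dir / f"network_{group}.graphml")
            export_network(net, out_dir / f"network_{group}.edges.tsv", fmt="edge-tsv")
            top = top_cooccurrences(corr, k=cfg.top_k)
            report_networks[group] = {
                "nodes": net.graph.number_of_nodes(),
                "edges": net.graph.number_of_edges(),
                "min_frequency": min_freq,
                "top": [
                    {"term_a": a, "term_b": b, "cocorrelation": round(v, 6)}
                    for a, b, v in top
                ],
            }
            logger.info(
                "network %s: %d nodes, %d edges", group,
                net.graph.number_of_nodes(), net.graph.number_of_edges(),
            )

        report = {
            "version": __version__,
            "config": cfg.to_dict(),
            "config_fingerprint": cfg.fingerprint(),
            "n_patients": len(records),
            "threshold_days": groups.threshold_days,
            "n_early": groups.n_early,
            "n_late": groups.n_late,
            "n_terms": dtm.shape[1],
            "trigger_table_top": json.loads(
                table.head(cfg.top_k).to_json(orient="records")
            ),
            "networks": report_networks,
        }
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
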