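"""End-to-end orchestration: read → trim → align → classify → conserve →
spread → write, with a manifest of artifacts and stage counts.

Every report written here is free of timestamps, so re-running with the
same configuration and seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io_formats
from .anchor_align import AlignParams, build_anchored_alignment
from .conservation import (
    ReferenceResidueSet,
    plectasin_record,
    score_mechanism_residues,
)
from .io_formats import LineageTable, PeptideRecord
from .scaffold import DEFAULT_SCAFFOLD_CONFIG, ScaffoldConfig, trim_to_mature
from .subfamily import DEFAULT_CLASSIFIER_CONFIG, ClassifierConfig, classify, summarize_calls
from .taxonomy import spread_by_clade, trans_kingdom_flag

logger = logging.getLogger("csab")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for exit-message discipline."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, capturable in a single YAML file."""

    input_fasta: Optional[Path] = None
    lineage_tsv: Optional[Path] = None
    tree_newick: Optional[Path] = None
    out_dir: Path = Path("csab_out")
    reference_fasta: Optional[Path] = None
    scaffold: ScaffoldConfig = field(default_factory=ScaffoldConfig)
    align: AlignParams = field(default_factory=AlignParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    max_nloop: int = 12
    max_tail: int = 6
    conservation_scheme: str = "classes"
    run_conservation: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, klass in (
            ("scaffold", ScaffoldConfig),
            ("align", AlignParams),
            ("classifier", ClassifierConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                for field_name in ("loop_windows", "mature_length_bounds", "aliphatic_offsets"):
                    if field_name in sub and isinstance(sub[field_name], list):
                        sub[field_name] = tuple(
                            tuple(x) if isinstance(x, list) else x for x in sub[field_name]
                        )
                kwargs[key] = klass(**sub)
        for key in ("input_fasta", "lineage_tsv", "tree_newick", "out_dir", "reference_fasta"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)


def _config_echo(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (frozenset, set)):
            return sorted(obj)
        if isinstance(obj, tuple):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        return obj

    return {
        f.name: encode(getattr(config, f.name)) for f in dataclasses.fields(config)
    }


def _load_reference(config: RunConfig) -> PeptideRecord:
    if config.reference_fasta is None:
        return plectasin_record()
    records = io_formats.read_fasta(config.reference_fasta)
    if not records:
        raise PipelineError("conservation", f"empty reference FASTA {config.reference_fasta}")
    return records[0]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full comparative analysis; returns the manifest dict.

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> dict:
    artifacts: dict[str, str] = {}
    manifest: dict = {"seed": config.seed, "config": _config_echo(config)}

    # --- read ---------------------------------------------------------
    if config.input_fasta is None:
        raise PipelineError("read", "no input FASTA configured")
    try:
        records = io_formats.read_fasta(config.input_fasta)
    except (OSError, ValueError) as exc:
        raise PipelineError("read", str(exc)) from exc
    if not records:
        raise PipelineError("read", f"no sequences in {config.input_fasta}")
    logger.info("read %d records from %s", len(records), config.input_fasta)

    # --- trim ---------------------------------------------------------
    matured, excluded = [], []
    for rec in records:
        mature = trim_to_mature(
            rec, config.scaffold, max_nloop=config.max_nloop, max_tail=config.max_tail
        )
        if mature is None:
            excluded.append(rec.id)
            logger.warning("excluded %s: no CSαβ scaffold found", rec.id)
        else:
            matured.append(mature)
    maturation = pd.DataFrame.from_records(
        [
            {
                "id": m.id,
                "mature_start": m.mature_start,
                "mature_end": m.mature_end,
                **{f"C{i + 1}": p for i, p in enumerate(m.scaffold.cys_positions)},
                "status": "accepted",
            }
            for m in matured
        ]
        + [{"id": rid, "status": "excluded"} for rid in excluded]
    )
    io_formats.write_tsv(maturation, out_dir / "maturation.tsv")
    artifacts["maturation"] = "maturation.tsv"
    if not matured:
        raise PipelineError("trim", "no record passed scaffold detection")

    # --- align --------------------------------------------------------
    reference = None
    rows_for_alignment = list(matured)
    if config.run_conservation:
        ref_record = _load_reference(config)
        if ref_record.id not in {m.id for m in matured}:
            reference = trim_to_mature(
                ref_record, config.scaffold,
                max_nloop=config.max_nloop, max_tail=config.max_tail,
            )
            if reference is None:
                raise PipelineError(
                    "conservation",
                    f"reference {ref_record.id!r} has no detectable scaffold",
                )
            rows_for_alignment.append(reference)
        ref_id = ref_record.id
    aln = build_anchored_alignment(rows_for_alignment, config.align)
    io_formats.write_aligned_fasta(aln.ids, aln.rows, out_dir / "alignment.afa")
    block_map = pd.DataFrame.from_records(
        [
            {"segment": name, "start_col": start, "end_col": end}
            for name, (start, end) in zip(
                ["nloop", "loop12", "loop23", "loop34", "loop45", "loop56", "tail"],
                aln.segment_blocks,
            )
        ]
        + [
            {"segment": f"anchor_C{i + 1}", "start_col": col, "end_col": col + 1}
            for i, col in enumerate(aln.anchor_columns)
        ]
    )
    io_formats.write_tsv(block_map, out_dir / "block_map.tsv")
    artifacts["alignment"] = "alignment.afa"
    artifacts["block_map"] = "block_map.tsv"

    # --- classify -----------------------------------------------------
    calls = [classify(m, config.classifier) for m in matured]
    calls_frame = pd.DataFrame.from_records([dataclasses.asdict(c) for c in calls])
    io_formats.write_tsv(calls_frame, out_dir / "calls.tsv")
    summary = summarize_calls(calls)
    io_formats.write_json(summary, out_dir / "summary.json")
    artifacts["calls"] = "calls.tsv"
    artifacts["summary"] = "summary.json"

    # --- conserve -----------------------------------------------------
    if config.run_conservation:
        try:
            refset = (
                ReferenceResidueSet.plectasin()
                if ref_id == "plectasin"
                else ReferenceResidueSet.for_record(_load_reference(config))
            )
            report = score_mechanism_residues(
                aln, refset, calls, scheme=config.conservation_scheme
            )
        except (LookupError, ValueError) as exc:
            raise PipelineError("conservation", str(exc)) from exc
        io_formats.write_tsv(report.long, out_dir / "conservation.tsv")
        io_formats.write_tsv(report.per_position, out_dir / "conservation_summary.tsv")
        artifacts["conservation"] = "conservation.tsv"
        artifacts["conservation_summary"] = "conservation_summary.tsv"

    # --- spread -------------------------------------------------------
    if config.lineage_tsv is not None:
        try:
            lineages = io_formats.read_lineage_tsv(config.lineage_tsv)
        except (OSError, ValueError) as exc:
            raise PipelineError("spread", str(exc)) from exc
        root, unplaced = spread_by_clade(calls, lineages)
        spread = {
            "tree": root.to_dict(),
            "unplaced": unplaced,
            "trans_kingdom": {
                label: trans_kingdom_flag(root, label) for label in ("GXGCP", "XTCD")
            },
        }
        io_formats.write_json(spread, out_dir / "spread.json")
        artifacts["spread"] = "spread.json"
        if config.tree_newick is not None:
            newick = Path(config.tree_newick).read_text()
            per_taxon: dict[str, set] = {}
            for call in calls:
                if call.taxon_id and call.label in ("GXGCP", "XTCD"):
                    per_taxon.setdefault(call.taxon_id, set()).add(call.label)
            result = io_formats.write_tree_annotation(newick, per_taxon, out_dir)
            artifacts["tree_annotation"] = "tree_annotation.tsv"
            artifacts["skipped_leaves"] = "skipped_leaves.txt"

    # --- manifest -----------------------------------------------------
    manifest["counts"] = {
        "read": len(records),
        "scaffold_accepted": len(matured),
        "excluded": len(excluded),
        "calls": len(calls),
    }
    manifest["artifacts"] = artifacts
    io_formats.write_json(manifest, out_dir / "manifest.json")
    return manifest
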