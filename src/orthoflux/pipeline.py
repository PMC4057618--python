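"""End-to-end orchestration: rbh -> conserve -> filter -> fba.

The pipeline owns no stage logic; it validates a single YAML-loadable
config, runs the four stages in fixed order, writes one TSV per stage with
a commented header carrying the config hash, and records a manifest with
per-stage input/output checksums. Re-running with identical config and
inputs reproduces identical stage outputs; stages whose recorded output
checksums still match are skipped (cheap resume).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError  # noqa: F401

from . import io as ofio
from .annotation import EnzymeAnnotation, ReactionChem, run_filter_cascade
from .conservation import (
    active_site_conserved,
    conservation_block,
    pair_conserved,
)
from .fba import (
    BiomassAugmentation,
    load_model,
    simulate_knockout_panel,
)
from .orthology import (
    AlignerConfig,
    all_vs_all,
    best_hit_per_query,
    classify_queries,
    reciprocal_best_hits,
)
from .records import InvalidInputError, Species

STAGE_ORDER = ("rbh", "conserve", "filter", "fba")


class PipelineConfigError(ValueError):
    pass


class DataValidationError(ValueError):
    pass


class AugmentSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    requirements: dict[str, float] = Field(default_factory=dict)
    mode: str = "coefficient"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    query_fasta: str
    db_fasta: str
    fwd_hits: Optional[str] = None
    rev_hits: Optional[str] = None
    sites: Optional[str] = None
    candidates: Optional[str] = None
    yeast_annotations: Optional[str] = None
    model: Optional[str] = None
    knockouts: list[str] = Field(default_factory=list)
    augment: Optional[AugmentSpec] = None
    evalue: float = 1e-5
    min_bit_margin: float = 50.0
    max_second_ratio: float = 0.9
    growth_epsilon: float = 1e-6
    outdir: str = "orthoflux_out"
    seed: int = 0
    skip: list[str] = Field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls(**raw)
        except (ValidationError, yaml.YAMLError) as exc:
            raise PipelineConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# orthoflux config_hash={config_hash}\n")
        df.to_csv(handle, sep="\t", index=False)


def read_sites_tsv(path) -> dict[str, list[int]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.accession), []).append(int(row.site_position))
    return out


def read_annotation_tsv(path) -> dict[str, EnzymeAnnotation]:
    """Annotation TSV: accession, pathways ('|'-joined), substrate_ids,
    product_ids (compound ids '|'-joined, CID:/SID: prefixed)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        split = lambda cell: frozenset(
            t.strip().replace(": ", ":")
            for t in str(cell).split("|")
            if t.strip()
        )
        out[row.accession] = EnzymeAnnotation(
            accession=row.accession,
            pathways=split(row.pathways),
            reactions=frozenset(
                [
                    ReactionChem(
                        substrates=split(row.substrate_ids),
                        products=split(row.product_ids),
                    )
                ]
            ),
        )
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute the pipeline; return the manifest (also written to disk).

    Stage hard-errors abort with the stage name; config problems surface
    before any stage runs.
    """
    outdir = Path(config.outdir)
    skip = set(config.skip)
    unknown = skip - set(STAGE_ORDER)
    if unknown:
        raise PipelineConfigError(f"unknown stages in skip: {sorted(unknown)}")
    # pre-flight: every enabled stage must have its inputs
    for path_attr in ("query_fasta", "db_fasta"):
        if not Path(getattr(config, path_attr)).exists():
            raise PipelineConfigError(
                f"{path_attr} does not exist: {getattr(config, path_attr)}"
            )
    if "conserve" not in skip and config.sites is None:
        raise PipelineConfigError("conserve stage enabled but no sites file")
    if "filter" not in skip and (
        config.candidates is None or config.yeast_annotations is None
    ):
        raise PipelineConfigError(
            "filter stage enabled but candidates/yeast_annotations missing"
        )
    if "fba" not in skip and config.model is None:
        raise PipelineConfigError("fba stage enabled but no model path")
    for attr in ("sites", "candidates", "yeast_annotations", "model"):
        value = getattr(config, attr)
        if value is not None and not Path(value).exists():
            raise PipelineConfigError(f"{attr} does not exist: {value}")

    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "tool": "orthoflux 0.1.0",
        "config_hash": chash,
        "stages": {},
    }
    prior: dict = {}
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        try:
            prior = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prior = {}

    def record(stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs},
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def resumable(stage: str, outputs: list[Path]) -> bool:
        if prior.get("config_hash") != chash:
            return False
        recorded = prior.get("stages", {}).get(stage, {}).get("outputs", {})
        return bool(recorded) and all(
            Path(p).exists() and _sha256(Path(p)) == digest
            for p, digest in recorded.items()
        ) and {str(p) for p in outputs} == set(recorded)

    # ---------------------------------------------------------------- rbh
    human = ofio.read_fasta(config.query_fasta, Species.HUMAN)
    yeast = ofio.read_fasta(config.db_fasta, Species.YEAST)
    aligner = AlignerConfig()
    if config.fwd_hits and config.rev_hits:
        fwd_hits = ofio.read_hit_table(config.fwd_hits)
        rev_hits = ofio.read_hit_table(config.rev_hits)
    else:
        fwd_hits = all_vs_all(human, yeast, aligner)
        rev_hits = all_vs_all(yeast, human, aligner)
    forward = best_hit_per_query(fwd_hits, config.evalue)
    reverse = best_hit_per_query(rev_hits, config.evalue)
    pairs = reciprocal_best_hits(forward, reverse)
    classification = classify_queries(sorted(human), forward, reverse)

    pairs_path = outdir / "pairs.tsv"
    class_path = outdir / "classification.tsv"
    if not resumable("rbh", [pairs_path, class_path]):
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "human_acc": p.human_acc,
                        "yeast_acc": p.yeast_acc,
                        "fwd_bits": round(p.forward_hit.bit_score, 1),
                        "rev_bits": round(p.reverse_hit.bit_score, 1),
                        "fwd_evalue": f"{p.forward_hit.e_value:.3g}",
                    }
                    for p in pairs
                ],
                columns=[
                    "human_acc",
                    "yeast_acc",
                    "fwd_bits",
                    "rev_bits",
                    "fwd_evalue",
                ],
            ),
            pairs_path,
            chash,
        )
        _write_tsv(
            pd.DataFrame(
                sorted(classification.labels.items()),
                columns=["accession", "label"],
            ),
            class_path,
            chash,
        )
    record(
        "rbh",
        [Path(config.query_fasta), Path(config.db_fasta)],
        [pairs_path, class_path],
    )

    conservation_by_acc: dict[str, bool] = {}
    if "conserve" not in skip:
        site_map = read_sites_tsv(config.sites)
        rows = []
        for pair in pairs:
            human_sites = site_map.get(pair.human_acc, [])
            yeast_sites = site_map.get(pair.yeast_acc, [])
            if not human_sites:
                continue
            mappings = active_site_conserved(pair, human_sites, yeast_sites)
            conservation_by_acc[pair.human_acc] = pair_conserved(mappings)
            for m in mappings:
                block = (
                    conservation_block(pair.forward_hit, m.column).block_string
                    if m.column >= 0
                    else ""
                )
                rows.append(
                    {
                        "human_acc": pair.human_acc,
                        "yeast_acc": pair.yeast_acc,
                        "human_site": m.human_pos,
                        "yeast_site": m.yeast_pos if m.yeast_pos else "GAP",
                        "conserved": m.conserved,
                        "block": block,
                        "note": m.note,
                    }
                )
        cons_path = outdir / "conservation.tsv"
        if not resumable("conserve", [cons_path]):
            _write_tsv(
                pd.DataFrame(
                    rows,
                    columns=[
                        "human_acc",
                        "yeast_acc",
                        "human_site",
                        "yeast_site",
                        "conserved",
                        "block",
                        "note",
                    ],
                ),
                cons_path,
                chash,
            )
        record("conserve", [Path(config.sites)], [cons_path])

    if "filter" not in skip:
        candidates = read_annotation_tsv(config.candidates)
        yeast_ann = read_annotation_tsv(config.yeast_annotations)
        hit_tables: dict[str, list] = {}
        for hit in fwd_hits:
            hit_tables.setdefault(hit.query_id, []).append(hit)
        try:
            report = run_filter_cascade(
                candidates,
                pairs,
                conservation_by_acc,
                hit_tables,
                yeast_ann,
                min_bit_margin=config.min_bit_margin,
                max_second_ratio=config.max_second_ratio,
            )
        except InvalidInputError as exc:
            raise DataValidationError(f"filter stage: {exc}") from exc
        rows = [
            {"stage": stage, "n_survivors": len(report.survivors[stage]),
             "survivors": "|".join(report.survivors[stage])}
            for stage in report.stages
        ]
        filt_path = outdir / "filter_report.tsv"
        drop_path = outdir / "filter_exclusions.tsv"
        if not resumable("filter", [filt_path, drop_path]):
            _write_tsv(pd.DataFrame(rows), filt_path, chash)
            _write_tsv(
                pd.DataFrame(
                    sorted(report.exclusions.items()),
                    columns=["accession", "reason"],
                ),
                drop_path,
                chash,
            )
        record(
            "filter",
            [Path(config.candidates), Path(config.yeast_annotations)],
            [filt_path, drop_path],
        )

    if "fba" not in skip:
        model = load_model(config.model)
        variants: dict[str, Optional[BiomassAugmentation]] = {"original": None}
        if config.augment is not None and config.augment.requirements:
            variants["augmented"] = BiomassAugmentation(
                requirements=dict(config.augment.requirements),
                mode=config.augment.mode,
            )
        outcomes = simulate_knockout_panel(
            model,
            config.knockouts,
            augmentations=variants,
            epsilon=config.growth_epsilon,
        )
        panel_path = outdir / "panel.tsv"
        if not resumable("fba", [panel_path]):
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "target": o.target or "WT",
                            "kind": o.kind,
                            "biomass_variant": o.biomass_variant,
                            "growth_rate": f"{o.growth_rate:.6f}",
                            "classification": o.classification,
                            "wt_ratio": f"{o.wt_ratio:.4f}",
                            "disabled_reactions": "|".join(
                                o.disabled_reactions
                            ),
                        }
                        for o in outcomes
                    ]
                ),
                panel_path,
                chash,
            )
        record("fba", [Path(config.model)], [panel_path])

    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
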