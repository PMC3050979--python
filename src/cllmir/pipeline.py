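"""End-to-end orchestration of the profiling analysis.

Stage order: normalize -> markers -> signature (when activated samples
are present) -> set enrichment (up and down sets independently) ->
clinical associations -> survival screen -> clustering. Every artifact
is written as plain text (TSV/CSV/JSON) and listed, with its SHA-256
checksum, in ``manifest.json``; a rerun with the same inputs and
configuration is byte-identical. Stages whose required sample groups
are absent are skipped with a logged reason; malformed inputs fail
before any stage runs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .cluster import hierarchical_order
from .enrichment import gsea_permutation_test
from .markers import (
    bh_adjust,
    clinical_association,
    derive_activation_signature,
    marker_selection,
)
from .preprocess import DEFAULT_EXCLUSIONS, normalize_matrix
from .rtpcr import delta_delta_ct
from .signature import MiRNASignature, signature_from_gmt, write_gmt
from .survival import survival_screen

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("cllmir")

STAGES = (
    "normalize",
    "markers",
    "signature",
    "gsea",
    "associations",
    "survival",
    "cluster",
)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (paths + thresholds)."""

    matrix: str
    samples: str
    outdir: str
    sets: str | None = None       # GMT; used when no activated samples
    ct_table: str | None = None   # optional RT-PCR stage
    exclusions: tuple = DEFAULT_EXCLUSIONS
    alpha: float = 0.05
    fdr_threshold: float = 0.10
    n_perm: int = 1000
    weight: float = 1.0
    min_leaf_frac: float = 0.2
    min_leaf_floor: int = 5
    class1: str = "control_B"
    seed: int = 0
    stages: tuple = STAGES

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.fdr_threshold < 1:
            raise ValueError("alpha and fdr_threshold must lie in (0, 1)")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Bundle:
    """Collects artifacts, their paths, and per-stage status."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.artifacts: dict[str, Path] = {}
        self.stage_status: dict[str, str] = {}
        self.objects: dict[str, object] = {}

    def add(self, key: str, path: Path, obj=None):
        self.artifacts[key] = path
        if obj is not None:
            self.objects[key] = obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the result bundle.

    The bundle maps stage artifacts to in-memory objects and recorded
    paths; ``manifest.json`` in the output directory lists inputs,
    configuration, and every written file with its checksum.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        # parse all inputs up front: malformed input fails before stages run
        raw = io.read_matrix(config.matrix)
        table = io.read_sample_table(config.samples)
        user_sets = (
            signature_from_gmt(config.sets) if config.sets is not None else None
        )
        ct = io.read_ct_table(config.ct_table) if config.ct_table else None
        return _run_stages(config, raw, table, user_sets, ct, outdir, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config, raw, table, user_sets, ct, outdir: Path, log_path: Path):
    bundle = _Bundle(outdir)
    groups = table["group"]
    labels = groups.to_dict()
    enabled = set(config.stages)

    def done(stage, msg=""):
        bundle.stage_status[stage] = "completed"
        logger.info("stage %s completed %s", stage, msg)

    def skipped(stage, reason):
        bundle.stage_status[stage] = f"skipped: {reason}"
        logger.warning("stage %s skipped: %s", stage, reason)

    # ---- normalize -------------------------------------------------
    norm, provenance = normalize_matrix(raw, exclude=config.exclusions)
    p = outdir / "expression_normalized.tsv"
    io.write_matrix(norm, p)
    bundle.add("normalized", p, norm)
    p = outdir / "normalization_provenance.json"
    io.write_json(provenance, p)
    bundle.add("provenance", p, provenance)
    done("normalize", f"({norm.shape[0]} features x {norm.shape[1]} samples)")

    has_cll = (groups == "CLL").sum() >= 2
    has_ctl = (groups == "control_B").sum() >= 2
    has_act = (groups == "activated_B").sum() >= 2

    # ---- markers (CLL vs control) ---------------------------------
    if "markers" in enabled and has_cll and has_ctl:
        markers = marker_selection(
            norm,
            {s: g for s, g in labels.items() if g in ("CLL", "control_B")},
            class1=config.class1 if config.class1 in ("CLL", "control_B") else None,
        )
        p = outdir / "marker_table.tsv"
        markers.to_csv(p, sep="\t", index=False)
        bundle.add("markers", p, markers)
        done("markers")
    elif "markers" in enabled:
        skipped("markers", "needs >=2 CLL and >=2 control_B samples")

    # ---- signature -------------------------------------------------
    # note: with many confident members, the BH step-up threshold for
    # additional discoveries is lenient, so a large panel can admit an
    # occasional extra member at the designed false-discovery rate
    signature: MiRNASignature | None = None
    if "signature" in enabled and has_ctl and has_act:
        signature = derive_activation_signature(
            norm, labels, alpha=config.alpha
        )
        p = outdir / "activation_signature.gmt"
        write_gmt(signature, p)
        bundle.add("signature", p, signature)
        done(
            "signature",
            f"({len(signature.up)} up / {len(signature.down)} down)",
        )
    elif "signature" in enabled:
        skipped("signature", "needs >=2 control_B and >=2 activated_B samples")
        if user_sets is not None:
            signature = user_sets
            logger.info("using user-supplied gene sets for enrichment")

    # ---- set enrichment (up and down independently) ---------------
    if "gsea" in enabled and signature is not None and has_cll and has_ctl:
        cc_labels = {
            s: g for s, g in labels.items() if g in ("CLL", "control_B")
        }
        results = {}
        pvals = {}
        for direction, members in (("up", signature.up), ("down", signature.down)):
            present = set(members) & set(norm.index)
            if not present:
                logger.warning("no %s-set members on the panel; set skipped", direction)
                continue
            res = gsea_permutation_test(
                norm,
                cc_labels,
                present,
                n_perm=config.n_perm,
                weight=config.weight,
                seed=config.seed,
                class1=config.class1,
            )
            results[direction] = res
            pvals[direction] = res.nominal_p
        if pvals:
            qvals = bh_adjust(list(pvals.values()))
            for (direction, res), q in zip(results.items(), qvals):
                res.fdr_q = float(q)
        p = outdir / "gsea_results.json"
        io.write_json({d: r.to_dict() for d, r in results.items()}, p)
        bundle.add("gsea", p, results)
        for direction, res in results.items():
            trace = pd.DataFrame(
                {
                    "rank": np.arange(1, len(res.running_sum) + 1),
                    "feature": list(res.ranked.features),
                    "running_sum": res.running_sum,
                }
            )
            tp = outdir / f"gsea_running_sum_{direction}.csv"
            trace.to_csv(tp, index=False)
            bundle.add(f"gsea_trace_{direction}", tp, trace)
        done("gsea", f"(sets: {sorted(results)})")
    elif "gsea" in enabled:
        skipped("gsea", "needs a signature (derived or GMT) plus CLL and control_B")

    # ---- clinical associations ------------------------------------
    if "associations" in enabled and has_cll:
        cll_cols = [s for s in norm.columns if labels.get(s) == "CLL"]
        assoc_frames = []
        for cov in ("zap70", "igvh"):
            sub = table.loc[table["group"] == "CLL"]
            informative = sub[cov].replace("NA", np.nan).dropna()
            if informative.nunique() < 2:
                logger.warning("covariate %s constant/missing; skipped", cov)
                continue
            res = clinical_association(norm[cll_cols], sub, cov)
            res.insert(0, "covariate", cov)
            assoc_frames.append(res)
        if assoc_frames:
            assoc = pd.concat(assoc_frames, ignore_index=True)
            p = outdir / "clinical_associations.tsv"
            assoc.to_csv(p, sep="\t", index=False)
            bundle.add("associations", p, assoc)
            done("associations")
        else:
            skipped("associations", "no informative clinical covariates")
    elif "associations" in enabled:
        skipped("associations", "needs CLL samples")

    # ---- survival screen ------------------------------------------
    surv_ok = (
        has_cll
        and table.loc[table["group"] == "CLL", ["ttft_days", "event"]]
        .notna()
        .all(axis=1)
        .sum()
        >= 2
    )
    if "survival" in enabled and surv_ok:
        screen = survival_screen(
            norm,
            table,
            min_leaf_frac=config.min_leaf_frac,
            min_leaf_floor=config.min_leaf_floor,
            fdr_threshold=config.fdr_threshold,
        )
        p = outdir / "survival_screen.tsv"
        screen.to_csv(p, sep="\t", index=False)
        bundle.add("survival", p, screen)
        done("survival", f"({int(screen['significant'].sum())} hits)")
    elif "survival" in enabled:
        skipped("survival", "needs >=2 CLL samples with survival fields")

    # ---- RT-PCR relative quantification (optional input) ----------
    if ct is not None:
        control_ids = table.index[table["group"] == "control_B"]
        cal = [s for s in control_ids if s in set(ct["sample_id"])]
        if cal:
            rel = delta_delta_ct(ct, calibrator=cal)
            p = outdir / "rtpcr_relative_expression.tsv"
            rel.to_csv(p, sep="\t", index=False)
            bundle.add("rtpcr", p, rel)
            done("rtpcr")
        else:
            skipped("rtpcr", "no control_B calibrator samples in the Ct table")

    # ---- clustering ------------------------------------------------
    if "cluster" in enabled and norm.shape[0] >= 2 and norm.shape[1] >= 2:
        ordering = hierarchical_order(norm)
        p = outdir / "cluster_ordering.json"
        io.write_json(
            {
                "feature_order": ordering.feature_order,
                "sample_order": ordering.sample_order,
                "feature_heights": ordering.feature_heights,
                "sample_heights": ordering.sample_heights,
            },
            p,
        )
        bundle.add("cluster", p, ordering)
        done("cluster")
    elif "cluster" in enabled:
        skipped("cluster", "matrix too small to cluster")

    # ---- manifest --------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {
            name: {"path": str(path), "sha256": _sha256(Path(path))}
            for name, path in (
                ("matrix", config.matrix),
                ("samples", config.samples),
                ("sets", config.sets),
                ("ct_table", config.ct_table),
            )
            if path is not None
        },
        "stages": bundle.stage_status,
        "artifacts": {
            key: {"path": path.name, "sha256": _sha256(path)}
            for key, path in bundle.artifacts.items()
        },
    }
    io.write_json(manifest, outdir / "manifest.json")
    # fail loudly if any listed artifact went missing mid-run
    for key, path in bundle.artifacts.items():
        if not path.exists():
            raise RuntimeError(f"artifact {key} missing after write: {path}")

    return {
        "manifest": manifest,
        "objects": bundle.objects,
        "stage_status": bundle.stage_status,
        "outdir": str(outdir),
        "log": str(log_path),
    }
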