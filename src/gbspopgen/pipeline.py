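"""End-to-end pipeline: QC → diversity → LD → Ne history → structure.

One config drives all stages and produces the full report bundle as
TSVs whose layouts mirror the standard summary tables of a GBS
population survey (chromosome summary, LD decay bins, Ne trajectory,
FST matrix), plus a manifest with a config hash for provenance. Every
stage is also available standalone through the library or CLI, and
produces identical numbers either way.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import site_stats, tajima_d
from .io import (
    GenotypeMatrix,
    apply_qc_filters,
    chromosome_summary,
    read_popmap,
    read_vcf,
    write_vcf,
)
from .ld import DEFAULT_BINS, collect_pairs, decay_summary
from .ne import NeConfig, equal_count_bins, estimate_ne_trajectory
from .structure import ajk_matrix, nei_distance, pairwise_fst, pca_coords

logger = logging.getLogger("gbspopgen")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a flat YAML file."""

    vcf: str
    popmap: str
    out_dir: str
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    ld_max_distance_bp: int = 92_000_000
    ne_alpha: float = 2.0
    ne_beta: int = 1
    ne_mapping: str = "linear"
    ne_rec_rate_per_bp: float = 1e-8
    ne_min_pairs: int = 50
    ne_n_bins: int = 20
    ne_min_bp: int = 40_000
    ne_max_bp: int = 20_000_000
    pca_axes: int = 10
    ajk_min_sites: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage in order, writing the report bundle to cfg.out_dir.

    Returns a mapping of artifact name → path. A stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure remain on disk and the manifest flags the failed stage.
    """
    logging.getLogger("gbspopgen").setLevel(cfg.log_level.upper())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _stage(name: str):
        def deco(fn):
            def wrapped(*args):
                t0 = time.time()
                try:
                    result = fn(*args)
                except Exception as exc:
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    _write_manifest()
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.time() - t0, 3),
                }
                return result
            return wrapped
        return deco

    def _write_manifest():
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n")
        artifacts["manifest"] = path

    def _save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        artifacts[name] = path

    @_stage("qc")
    def qc():
        gm = read_vcf(cfg.vcf)
        pm = read_popmap(cfg.popmap)
        pm.validate_against(gm)
        filtered, report = apply_qc_filters(gm, cfg.maf_min, cfg.call_rate_min)
        _save("filter_report", report.to_frame())
        write_vcf(filtered, out / "filtered.vcf")
        artifacts["filtered_vcf"] = out / "filtered.vcf"
        _save("chromosome_summary", chromosome_summary(filtered))
        return filtered, pm

    @_stage("diversity")
    def diversity(gm):
        per_site, summary = site_stats(gm)
        _save("site_stats", per_site)
        taj = tajima_d(gm)
        summary = summary.join(taj.to_frame())
        _save("diversity_summary", summary)

    @_stage("ld")
    def ld(gm):
        pairs, n_undef = collect_pairs(gm, cfg.ld_max_distance_bp)
        bins, n_unbinned = decay_summary(pairs, DEFAULT_BINS)
        _save("ld_bins", bins)
        decay = bins[["mean_distance_bp", "mean_r2"]].dropna()
        _save("ld_decay_curve", decay)
        return pairs

    @_stage("ne")
    def ne(gm, pairs):
        ne_cfg = NeConfig(
            alpha=cfg.ne_alpha,
            beta=cfg.ne_beta,
            n_samples=gm.n_samples,
            mapping=cfg.ne_mapping,
            rec_rate_per_bp=cfg.ne_rec_rate_per_bp,
            min_pairs=cfg.ne_min_pairs,
        )
        bins = equal_count_bins(pairs, cfg.ne_n_bins, cfg.ne_min_bp, cfg.ne_max_bp)
        traj = estimate_ne_trajectory(bins, ne_cfg)
        table = traj.rename(
            columns={
                "t_rounded": "Generations Ago",
                "nt": "Ne",
                "mean_distance_bp": "Dist.",
                "mean_r2": "r2",
                "sd_r2": "r2 SD",
            }
        )[["Generations Ago", "Ne", "Dist.", "r2", "r2 SD"]] if not traj.empty else traj
        _save("ne_trajectory", table)

    @_stage("structure")
    def structure(gm, pm):
        fst = pairwise_fst(gm, pm)
        _save("fst_matrix", fst.to_frame(), index=True)
        (out / "fst_matrix.nex").write_text(fst.to_nexus())
        nei = nei_distance(gm, pm)
        _save("nei_matrix", nei.to_frame(), index=True)
        (out / "nei_matrix.nex").write_text(nei.to_nexus())
        artifacts["nei_nexus"] = out / "nei_matrix.nex"
        ajk = ajk_matrix(gm, cfg.ajk_min_sites)
        _save("ajk_matrix", ajk.to_frame(), index=True)
        pca = pca_coords(gm, cfg.pca_axes)
        coords = pca.to_frame()
        coords.insert(0, "population", [pm.assignments.get(s, "NA") for s in pca.sample_ids])
        _save("pca_coords", coords, index=True)
        pd.DataFrame(
            {"axis": range(1, len(pca.variance_fractions) + 1),
             "variance_fraction": pca.variance_fractions}
        ).pipe(lambda df: _save("pca_variance", df))

    gm, pm = qc()
    diversity(gm)
    pairs = ld(gm)
    ne(gm, pairs)
    structure(gm, pm)
    _write_manifest()
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
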