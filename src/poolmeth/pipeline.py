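"""End-to-end pipeline (filter -> pool -> reconstruct) with a run manifest.

Configuration precedence is handled by the CLI (flags > config file >
defaults); this module executes a fully resolved :class:`PipelineConfig`
and records, for reproducibility, the resolved parameters, input digests,
the record count every stage dropped, and the seed. Record counts are
conserved: ``sites_in == sites_out + sum(removed by each filter)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .core_io import (CpGCountTable, ReferenceMethylome, read_count_table,
                      read_manifest, read_reference_methylome)
from .errors import PoolmethError, ValidationError
from .filtering import (DEFAULT_MAX_CT_RATIO, DEFAULT_MIN_SNP_HITS,
                        DEFAULT_SMOOTH_WINDOW, cap_sample_coverage,
                        filter_samples_by_snp_hits, mutation_filter)
from .pooling import (estimate_deamination_profile, mle_methylation_map,
                      naive_pool, pooled_effective_deamination)
from .reconstruction import (DEFAULT_M0, DEFAULT_P0, DEFAULT_W_MAX,
                             reconstruct_map)
from .core_io import MethylationMap

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run."""

    manifest: str
    reference: str
    output: str
    method: str = "naive"               # naive | mle
    min_snp_hits: int = DEFAULT_MIN_SNP_HITS
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    max_ct_ratio: float = DEFAULT_MAX_CT_RATIO
    p0: float = DEFAULT_P0
    m0: float = DEFAULT_M0
    w_max: int = DEFAULT_W_MAX
    window: int | None = None           # override adaptive window sizing
    anchor_methylation: float = 1.0
    seed: int = 0
    run_manifest: str | None = None     # defaults to <output>.run.json

    def __post_init__(self) -> None:
        if self.method not in ("naive", "mle"):
            raise ValidationError(f"method must be naive or mle, got "
                                  f"{self.method!r}")


@dataclass
class RunManifest:
    """Machine-readable record of one run."""

    version: str
    parameters: dict
    input_digests: dict
    counts: dict
    seed: int

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[MethylationMap, RunManifest]:
    """Execute filter -> pool -> reconstruct and write map + run manifest."""
    out_path = Path(config.output)
    manifest_out = (Path(config.run_manifest) if config.run_manifest
                    else out_path.with_suffix(out_path.suffix + ".run.json"))
    try:
        records = read_manifest(config.manifest)
        reference = read_reference_methylome(config.reference)
        kept = filter_samples_by_snp_hits(records, config.min_snp_hits)
        counts: dict = {
            "samples_in": len(records),
            "samples_removed_snp_filter": len(records) - len(kept),
        }
        if not kept:
            raise ValidationError("no samples pass the SNP-hit filter")
        base = Path(config.manifest).parent
        tables: dict[str, CpGCountTable] = {}
        removed_by_cap = 0
        sites_per_sample = 0
        for rec in kept:
            path = Path(rec.path)
            if not path.is_absolute():
                path = base / path
            table = read_count_table(path)
            sites_per_sample += len(table)
            capped, _ = cap_sample_coverage(table, config.smooth_window)
            removed_by_cap += len(table) - len(capped)
            tables[rec.sample_id] = capped
        counts["sample_sites_read"] = sites_per_sample
        counts["sample_sites_removed_coverage_cap"] = removed_by_cap

        pooled = naive_pool(list(tables.values()))
        sites_in = len(pooled)
        pooled = mutation_filter(pooled, config.max_ct_ratio)
        counts["pooled_sites"] = sites_in
        counts["pooled_sites_removed_mutation_filter"] = sites_in - len(pooled)

        if config.method == "naive":
            result = reconstruct_map(
                pooled, reference, p0=config.p0, m0=config.m0,
                W_max=config.w_max, W=config.window,
                anchor_methylation=config.anchor_methylation,
            )
            map_ = result.map
            counts["window"] = result.window
            counts["effective_coverage"] = round(result.effective_coverage, 4)
            counts["deamination_rate"] = round(result.deamination_rate, 6)
        else:
            profile = estimate_deamination_profile(
                tables, reference, config.anchor_methylation)
            from .reconstruction import effective_coverage, window_size
            C = effective_coverage(pooled)
            pi = pooled_effective_deamination(profile)
            W = config.window or window_size(C, config.p0, config.m0, pi,
                                             config.w_max)
            frame = mle_methylation_map(tables, profile, W)
            map_ = MethylationMap(frame)
            counts["window"] = W
            counts["effective_coverage"] = round(C, 4)
            counts["deamination_rate"] = round(pi, 6)
        counts["sites_reconstructed"] = int(map_.present.shape[0])
        assert counts["pooled_sites"] == (
            len(pooled) + counts["pooled_sites_removed_mutation_filter"])

        map_.write(out_path)
        run = RunManifest(
            version=__version__,
            parameters={k: v for k, v in asdict(config).items()},
            input_digests={
                "manifest": _digest(config.manifest),
                "reference": _digest(config.reference),
            },
            counts=counts,
            seed=config.seed,
        )
        run.write(manifest_out)
        return map_, run
    except Exception:
        # remove partial outputs so a failed run leaves nothing behind
        for p in (out_path, manifest_out):
            if p.exists():
                p.unlink()
        raise
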