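"""Pipeline configuration: a single YAML file validated on load, so every
tolerance, threshold, and seed of a run is auditable in one place."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genome import BinnedGenome


@dataclass
class ModelSettings:
    n_states: int = 18
    marks: list[str] = field(default_factory=list)
    n_restarts: int = 5
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 200


@dataclass
class AnalysisSettings:
    state_names: dict[int, str] = field(default_factory=dict)
    bivalent_state: str = "TssBiv"
    flank_states: list[str] = field(
        default_factory=lambda: [
            "ReprPC", "ReprPCWk", "Quies", "Quies2", "Quies3", "Quies4", "QuiesG"
        ]
    )
    atac_threshold: float = 0.5
    wgbs_threshold_percent: float = 50.0
    chip_p_threshold: float = 1e-4
    n_draws: int = 100
    # Embedding parameters recorded for users who run an external UMAP on
    # the exported signal matrices (the embedding itself is out of scope).
    umap_enh: dict = field(
        default_factory=lambda: {"n_neighbors": 7, "min_dist": 0.5, "seed": 11}
    )
    umap_tssbiv: dict = field(
        default_factory=lambda: {"n_neighbors": 10, "min_dist": 0.04, "seed": 12}
    )


@dataclass
class PipelineConfig:
    genome: BinnedGenome
    biosamples: list[dict]  # biosample, tissue, timepoint, per-mark paths
    model: ModelSettings
    analysis: AnalysisSettings

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        gspec = raw.get("genome", {})
        bin_size = int(gspec.get("bin_size", 200))
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        genome = BinnedGenome(
            [(c["name"], int(c["length"])) for c in gspec.get("chromosomes", [])],
            bin_size,
        )
        biosamples = raw.get("biosamples", [])
        base = Path(path).parent
        for b in biosamples:
            for mark, p in b.get("tracks", {}).items():
                full = base / p
                if not full.exists():
                    raise FileNotFoundError(
                        f"biosample {b.get('biosample')}: track {mark} "
                        f"file not found: {full}"
                    )
        mspec = raw.get("model", {})
        model = ModelSettings(
            n_states=int(mspec.get("n_states", 18)),
            marks=list(mspec.get("marks", [])),
            n_restarts=int(mspec.get("n_restarts", 5)),
            seed=int(mspec.get("seed", 0)),
            tol=float(mspec.get("tol", 1e-4)),
            max_iter=int(mspec.get("max_iter", 200)),
        )
        aspec = raw.get("analysis", {})
        analysis = AnalysisSettings(
            state_names={int(k): v for k, v in aspec.get("state_names", {}).items()},
            bivalent_state=aspec.get("bivalent_state", "TssBiv"),
            flank_states=list(
                aspec.get("flank_states", AnalysisSettings().flank_states)
            ),
            atac_threshold=float(aspec.get("atac_threshold", 0.5)),
            wgbs_threshold_percent=float(aspec.get("wgbs_threshold_percent", 50.0)),
            chip_p_threshold=float(aspec.get("chip_p_threshold", 1e-4)),
            n_draws=int(aspec.get("n_draws", 100)),
        )
        return cls(genome, biosamples, model, analysis)
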