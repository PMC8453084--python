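"""Pipeline configuration: validated settings with paper- and desk-scale presets.

The ``paper`` preset mirrors the analysis scale the method was designed for
(492 subjects, 246 ROIs, 17 networks, 10-fold CV repeated 100 times, 6-mm
spheres, >50% overlap, 5000 permutations, FWE and FDR alpha 0.05). The
``desk`` preset keeps every statistical rule identical but shrinks the
repeat, permutation, gene and sample counts so a full run finishes on one
CPU in well under a minute per stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "SCALE_PRESETS"]

SCALE_PRESETS: dict[str, dict[str, Any]] = {
    "paper": dict(
        n_subjects=492, repeats=100, n_perm=5000,
        n_genes=20738, n_signal_genes=25,
        samples_per_donor=(363, 946),
    ),
    "desk": dict(
        n_subjects=250, repeats=5, n_perm=999,
        n_genes=500, n_signal_genes=25,
        samples_per_donor=(60, 150),
    ),
}


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; every default mirrors the paper-scale
    analysis except the sizes controlled by ``scale``."""

    seed: int | None = None
    scale: str = "desk"
    simulate: bool = True

    # inputs when simulate is False
    atlas_dir: str | None = None
    cohort_dir: str | None = None
    expression_dir: str | None = None
    gmt_path: str | None = None

    # prediction
    k: int = 10
    repeats: int = 5
    kernel: str = "linear"

    # annotation
    sphere_radius_mm: float = 6.0
    overlap_threshold: float = 0.5
    n_perm: int = 999
    fwe_method: str = "maxstat"
    alpha_fwe: float = 0.05
    alpha_fdr: float = 0.05

    # generator sizes (simulate=True)
    n_subjects: int = 250
    n_rois: int = 246
    n_networks: int = 17
    age_range: tuple[float, float] = (19.0, 80.0)
    important_network: int = 1
    n_donors: int = 6
    samples_per_donor: tuple[int, int] = (60, 150)
    n_genes: int = 500
    n_signal_genes: int = 25
    effect_size: float = 0.5
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)

    def __post_init__(self) -> None:
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}")

    @classmethod
    def with_scale(cls, scale: str, **overrides: Any) -> "PipelineConfig":
        params = dict(SCALE_PRESETS[scale], scale=scale, **overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("age_range", "samples_per_donor", "term_size_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        scale = raw.pop("scale", "desk")
        base = dict(SCALE_PRESETS[scale], scale=scale)
        base.update(raw)
        return cls(**base)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must specify a seed (no silent nondeterminism)")
        if not 2 <= self.k <= self.n_subjects:
            raise ValueError(f"k={self.k} incompatible with n={self.n_subjects}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.kernel not in ("linear", "linear+rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere radius must be positive")
        if not 0.0 <= self.overlap_threshold < 1.0:
            raise ValueError("overlap threshold must lie in [0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.fwe_method not in ("maxstat", "bonferroni"):
            raise ValueError(f"unknown FWE method {self.fwe_method!r}")
        for name in ("alpha_fwe", "alpha_fdr"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 1 <= self.important_network <= self.n_networks:
            raise ValueError("important_network outside 1..n_networks")
        if not self.simulate:
            for name in ("atlas_dir", "cohort_dir", "expression_dir", "gmt_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"simulate=False requires {name}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for key in ("age_range", "samples_per_donor", "term_size_range"):
            d[key] = list(d[key])
        return d
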