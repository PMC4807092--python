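"""Simulation configuration and deterministic random-number streams.

A single integer seed drives the whole experiment.  Every consumer of
randomness (truth generation, each regional library, the pooled library,
the in-silico mix, ...) derives its own independent stream from that seed
through a fixed, named spawn key, so adding or reordering samples never
perturbs the draws of earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SimulationConfig", "stream_rng"]


def stream_rng(seed: int, *key: object) -> np.random.Generator:
    """Return an independent Generator for the named stream under ``seed``.

    String key parts are mapped to integers via CRC32 so the mapping is
    stable across processes and platforms.
    """
    parts = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=parts))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-regional tumor experiment.

    Defaults emulate a four-region exome/transcriptome design: clonal
    (truncal) somatic variants centered at 40% VAF, subclonal variants at
    low VAF, ~137x exome coverage, and 18,161 coding genes with a small
    minority carrying region-specific expression effects.
    """

    n_regions: int = 4
    n_truncal: int = 60
    n_shared: int = 20
    n_private: int = 20
    n_germline_het: int = 200
    n_germline_hom: int = 100

    vaf_truncal_mean: float = 0.40
    vaf_truncal_sd: float = 0.08
    vaf_subclonal_range: tuple[float, float] = (0.02, 0.30)

    depth_mean: float = 137.0
    #: negative-binomial shape; 120 gives sd(depth) ~ 17 at mean 137
    depth_dispersion: float = 120.0
    error_rate: float = 1e-3

    # annotation-flag assignment probabilities
    frac_somatic_cosmic: float = 0.15
    frac_germline_cosmic: float = 0.02
    frac_panel: float = 0.10

    # expression model
    n_genes: int = 18161
    frac_de_genes: float = 0.05
    de_fold_range: tuple[float, float] = (2.0, 6.0)
    #: negative-binomial size parameter of per-gene counts (CV ~ 10% at 100)
    expr_dispersion: float = 100.0
    #: median and log-sd of the log-normal baseline gene means
    expr_median: float = 200.0
    expr_log_sigma: float = 1.5

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_shared > 0 and self.n_regions < 3:
            raise ValueError(
                "n_shared requires n_regions >= 3 (a shared variant occupies "
                "a strict subset of >= 2 regions)"
            )
        for name in (
            "n_truncal",
            "n_shared",
            "n_private",
            "n_germline_het",
            "n_germline_hom",
            "n_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "vaf_truncal_mean",
            "error_rate",
            "frac_de_genes",
            "frac_somatic_cosmic",
            "frac_germline_cosmic",
            "frac_panel",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.vaf_subclonal_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(
                f"vaf_subclonal_range must be an ordered pair in [0, 1], "
                f"got {self.vaf_subclonal_range}"
            )
        if self.de_fold_range[0] <= 1.0:
            raise ValueError("de_fold_range lower bound must be > 1")
        if self.de_fold_range[1] < self.de_fold_range[0]:
            raise ValueError("de_fold_range must be ordered")
        for name in ("depth_mean", "depth_dispersion", "expr_dispersion",
                     "expr_median", "expr_log_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.vaf_truncal_sd < 0:
            raise ValueError("vaf_truncal_sd must be >= 0")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vaf_subclonal_range"] = list(d["vaf_subclonal_range"])
        d["de_fold_range"] = list(d["de_fold_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("vaf_subclonal_range", "de_fold_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def rng(self, *key: object) -> np.random.Generator:
        return stream_rng(self.seed, *key)
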