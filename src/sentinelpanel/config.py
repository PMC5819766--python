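"""Run configuration: every tunable of the pipeline in one validated record."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

from .errors import ConfigError


@dataclass
class RunConfig:
    """Pipeline parameters with their documented defaults.

    var_fraction
        Fraction of total variance the retained eigengenes must explain (0.9).
    k
        Number of k-means experiment clusters for the diversity score (10).
    n_folds
        Study folds for the co-expression score and cross-validation (20).
    h
        Tree-cut height for 1 - |r| gene clustering (0.9).
    biweight_c
        Tukey biweight tuning constant (5).
    n
        Data-driven panel size (1500).
    q
        Minimum selected genes per pathway after refinement (3).
    lam
        Eigenvalue-ratio cutoff for extrapolation components (0.01).
    fc_threshold
        |log2FC| defining a "changed" entry for concordance (1.0 = 2-fold).
    top_fraction
        Fraction defining the top-by-magnitude significance sets (0.01).
    es_threshold, p_threshold
        Differential-pathway cutoffs: |ES| > 0.5 and KS p < 0.001.
    weight_exponent
        Running-sum hit weight exponent p (1; 0 gives the unweighted KS form).
    seed
        Master seed; all stage randomness derives from it.
    center
        Fold-change centering for PCA: "none" or "gene-mean".
    """

    var_fraction: float = 0.9
    k: int = 10
    n_folds: int = 20
    h: float = 0.9
    biweight_c: float = 5.0
    n: int = 1500
    q: int = 3
    lam: float = 0.01
    fc_threshold: float = 1.0
    top_fraction: float = 0.01
    es_threshold: float = 0.5
    p_threshold: float = 0.001
    weight_exponent: float = 1.0
    seed: int = 0
    center: str = "none"

    _RANGES = {
        "var_fraction": (0.0, 1.0, "()"),
        "k": (1, None, "[)"),
        "n_folds": (1, None, "[)"),
        "h": (0.0, 2.0, "(]"),
        "biweight_c": (0.0, None, "()"),
        "n": (1, None, "[)"),
        "q": (1, None, "[)"),
        "lam": (0.0, 1.0, "(]"),
        "fc_threshold": (0.0, None, "[)"),
        "top_fraction": (0.0, 1.0, "(]"),
        "es_threshold": (0.0, 1.0, "[)"),
        "p_threshold": (0.0, 1.0, "(]"),
        "weight_exponent": (0.0, None, "[)"),
    }

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi, mode) in self._RANGES.items():
            v = getattr(self, name)
            if lo is not None:
                ok = v > lo if mode[0] == "(" else v >= lo
                if not ok:
                    raise ConfigError(f"{name}={v} below allowed range")
            if hi is not None:
                ok = v < hi if mode[1] == ")" else v <= hi
                if not ok:
                    raise ConfigError(f"{name}={v} above allowed range")
        if self.center not in ("none", "gene-mean"):
            raise ConfigError(f"center={self.center!r} must be 'none' or 'gene-mean'")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        # accept the parameter's mathematical name too
        data = {("lam" if k == "lambda" else k): v for k, v in data.items()}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable short hash of the configuration, for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
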