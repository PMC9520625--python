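"""Sample entropy and entropy-guided choice of the VMD mode count.

Sample entropy (SampEn) of a series is -ln(A/B), where B counts pairs
of z-length templates whose Chebyshev distance is within a tolerance r,
and A counts the same pairs at length z+1; self-matches are excluded
(Richman-Moorman estimator).  Regular series score low, complex ones
high.  An appropriate VMD mode count M yields modes that are individually
regular, so M is chosen as the candidate minimising the mean SampEn of
the resulting modes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .vmd import VMDConfig, VMDResult, vmd_decompose

__all__ = ["SampEnConfig", "sample_entropy", "mean_mode_entropy", "select_M"]


@dataclass
class SampEnConfig:
    embed_dim: int = 2                  # template length z
    r_mode: str = "relative_sd"         # "relative_sd" | "absolute"
    r_value: float = 0.2                # factor of SD, or absolute tolerance
    candidates: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.r_mode not in ("relative_sd", "absolute"):
            raise ValueError("r_mode must be 'relative_sd' or 'absolute'")
        if self.r_value <= 0:
            raise ValueError("r_value must be positive")
        if any(m < 1 for m in self.candidates):
            raise ValueError("all candidate mode counts must be >= 1")


def _match_count(series: np.ndarray, z: int, r: float, n_templates: int) -> int:
    """Pairs (i < j) of z-length templates within Chebyshev distance r.

    ``n_templates`` fixes how many starting indices are used so that the
    z and z+1 counts run over the same template set.
    """
    idx = np.arange(n_templates)
    templates = series[idx[:, None] + np.arange(z)[None, :]]   # (n, z)
    dist = np.max(
        np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1
    )
    within = dist <= r
    return int((within.sum() - n_templates) // 2)              # exclude self-matches


def sample_entropy(series: np.ndarray, config: SampEnConfig | None = None) -> float:
    """SampEn of a 1-D series; returns +inf when no (z+1)-matches exist."""
    config = config or SampEnConfig()
    x = np.asarray(series, dtype=float).ravel()
    z = config.embed_dim
    if x.size < z + 2:
        raise ValueError(f"series length {x.size} too short for embed_dim {z}")

    if config.r_mode == "relative_sd":
        sd = float(np.std(x))
        if sd == 0.0:
            return 0.0      # constant series: every template matches at all dims
        r = config.r_value * sd
    else:
        r = config.r_value

    n_templates = x.size - z    # shared by both dimensions for comparability
    b = _match_count(x, z, r, n_templates)
    a = _match_count(x, z + 1, r, n_templates)
    if b == 0:
        raise ValueError("no template matches at dimension z; SampEn undefined")
    if a == 0:
        warnings.warn(
            "no template matches at dimension z+1; returning +inf", stacklevel=2
        )
        return math.inf
    return -math.log(a / b)


def mean_mode_entropy(result: VMDResult, config: SampEnConfig | None = None) -> float:
    """Arithmetic mean SampEn over the modes of a decomposition.

    Each mode resolves its own tolerance (r relative to its own SD by
    default); an infinite per-mode entropy propagates to the mean.
    """
    config = config or SampEnConfig()
    if result.n_modes < 1:
        raise ValueError("decomposition has no modes")
    values = [sample_entropy(result.modes[m], config) for m in range(result.n_modes)]
    if any(math.isinf(v) for v in values):
        return math.inf
    return float(np.mean(values))


def select_M(
    signal: np.ndarray,
    vmd_config: VMDConfig | None = None,
    config: SampEnConfig | None = None,
    *,
    return_entropies: bool = False,
):
    """Choose the VMD mode count by minimum mean mode entropy.

    Decomposes ``signal`` once per candidate M, scores each decomposition
    by :func:`mean_mode_entropy`, and returns the argmin (ties broken
    toward the smallest M).  With ``return_entropies`` the per-candidate
    entropy map is returned alongside.
    """
    vmd_config = vmd_config or VMDConfig()
    config = config or SampEnConfig()
    entropies: dict[int, float] = {}
    for m in config.candidates:
        cfg = VMDConfig(
            n_modes=m,
            alpha=vmd_config.alpha,
            tau=vmd_config.tau,
            eps=vmd_config.eps,
            max_iter=vmd_config.max_iter,
            init_omega=vmd_config.init_omega,
        )
        entropies[m] = mean_mode_entropy(vmd_decompose(signal, cfg), config)
    finite = {m: v for m, v in entropies.items() if math.isfinite(v)}
    if not finite:
        raise ValueError("sample entropy undefined (infinite) for every candidate M")
    best = min(sorted(finite), key=lambda m: finite[m])
    if return_entropies:
        return best, entropies
    return best
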