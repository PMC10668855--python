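"""Lightweight result containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood model fit."""

    loglik: float
    params: dict = field(default_factory=dict)
    site_logliks: np.ndarray | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def flag(self, msg: str) -> None:
        self.flags.append(msg)
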