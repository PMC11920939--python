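"""Exception types shared across the package."""

from __future__ import annotations

import numpy as np


class GLVSimError(Exception):
    """Base class for all glvsim-specific errors."""


class InvalidRichnessError(GLVSimError, ValueError):
    """Species richness S is too small or not a positive integer."""


class InvalidConnectanceError(GLVSimError, ValueError):
    """Connectance c lies outside [0, 1]."""


class DimensionMismatchError(GLVSimError, ValueError):
    """Matrix/vector shapes are inconsistent."""


class DomainError(GLVSimError, ValueError):
    """A state vector violates the admissible domain of the dynamics."""


class UndefinedStatisticError(GLVSimError, ValueError):
    """A summary statistic is undefined for the given survivor set."""


class IntegrationError(GLVSimError, RuntimeError):
    """The ODE solver failed; carries whatever trajectory was produced."""

    def __init__(self, message: str, t: "np.ndarray | None" = None,
                 y: "np.ndarray | None" = None):
        super().__init__(message)
        self.partial_t = t
        self.partial_y = y
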