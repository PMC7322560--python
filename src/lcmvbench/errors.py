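"""Exception hierarchy.

Rank problems and geometric impossibilities must surface loudly: a beamformer
that silently pseudo-inverts a rank-deficient covariance produces maps that
look plausible and localize wrongly, which is exactly the failure mode this
package exists to study.
"""


class LCMVBenchError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LCMVBenchError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(LCMVBenchError, ValueError):
    """A geometric quantity is outside the physical domain of a formula
    (e.g. a sensor inside the conducting sphere, a source at the origin)."""


class EmptyGridError(LCMVBenchError, ValueError):
    """No grid point satisfies the requested constraints."""


class DegenerateDataError(LCMVBenchError, ValueError):
    """Data are degenerate for the requested operation (all trials rejected,
    zero covariance, zero effective rank, non-positive-definite matrix)."""


class SingularModelError(LCMVBenchError, ValueError):
    """A model matrix (local leadfield Gram) is singular and the operation
    refuses to silently pseudo-invert it."""


class SilentSourceError(LCMVBenchError, ValueError):
    """The requested source orientation is magnetically silent (zero
    leadfield), e.g. radial in a spherical conductor."""
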