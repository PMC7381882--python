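"""Package exception hierarchy."""


class LAAViewError(Exception):
    """Base class for package errors."""


class ParameterError(LAAViewError, ValueError):
    """Invalid anatomy or configuration parameters."""


class GenerationError(LAAViewError, RuntimeError):
    """Mesh construction failed (e.g. watertightness could not be achieved)."""


class GeometryError(LAAViewError, RuntimeError):
    """A geometric operation has no valid result (empty section, no crossing...)."""


class FormatError(LAAViewError, ValueError):
    """Malformed external file (STL / sidecar)."""


class FeasibilityError(LAAViewError, RuntimeError):
    """No gantry pose inside the feasibility box satisfies the constraints."""
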