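"""Exception hierarchy for implantbar."""


class ModelError(ValueError):
    """Base class for all modelling errors."""


class LayoutError(ModelError):
    """Implant layout is malformed (wrong count, coincident points, ...)."""


class ParameterError(ModelError):
    """A physical parameter is out of its admissible range."""


class SymmetryError(ModelError):
    """Layout lacks the sagittal mirror symmetry the closed form requires."""


class RankError(ModelError):
    """Assembled rigid-body stiffness is singular (degenerate layout)."""
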