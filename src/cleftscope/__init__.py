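"""cleftscope: analysis toolkit for protein-ligand cleft interactions.

Subpackages cover structure/trajectory I/O, synthetic fixture generation,
geometric interaction fingerprinting (hydrogen bonds, salt bridges,
pi-pi stacking), NOE-style effective proton distances, superposition-based
trajectory geometry, a well-tempered metadynamics engine on toy potentials,
and end-point binding free-energy bookkeeping.
"""

__version__ = "0.1.0"

KB = 0.0019872
"""Boltzmann constant in kcal mol^-1 K^-1, fixed project-wide."""


class CleftscopeError(Exception):
    """Base class for all package errors."""


class ParseError(CleftscopeError):
    """A file did not conform to its declared dialect."""


class EmptyInputError(CleftscopeError):
    """An input contained no usable records."""


class AnnotationError(CleftscopeError):
    """Topology annotation failed (unknown residue, missing template atoms)."""


class SelectionError(CleftscopeError):
    """An atom/group selector resolved to nothing."""


class GeometryError(CleftscopeError):
    """A geometric operation received degenerate input."""


class UsageError(CleftscopeError):
    """An operation was called outside its contract."""


class SpecificationError(CleftscopeError):
    """A fixture specification is infeasible."""


class RunError(CleftscopeError):
    """A dynamics run diverged or otherwise failed."""
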