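"""Named exception types shared across the toolkit."""


class OligobandError(Exception):
    """Base class for all toolkit errors."""


class UnknownChromosomeError(OligobandError):
    """A record references a chromosome id absent from the genome build."""


class CoordinateError(OligobandError):
    """A genomic coordinate falls outside its chromosome."""


class InfeasibleDesignError(OligobandError):
    """Probe window selection cannot satisfy the stated constraints."""


class WindowSizeError(OligobandError):
    """An oligo window has the wrong number of candidates."""


class ColourTokenError(OligobandError):
    """An invalid or inappropriate colour token was supplied."""


class PanelError(OligobandError):
    """A chromosome panel violates a structural requirement."""


class SequenceError(OligobandError):
    """A nucleotide sequence contains invalid characters or lengths."""


class SelectionError(OligobandError):
    """Orthogonal-set selection could not reach the requested size."""


class LayoutError(OligobandError):
    """Oligo layout and sequence lengths disagree."""


class ProfileError(OligobandError):
    """Intensity-profile extraction failed (path outside image, channel mismatch)."""


class SignatureError(OligobandError):
    """A signature violates a structural requirement (overlapping bands)."""


class SchemeError(OligobandError):
    """A colour scheme is unusable for the requested operation."""


class RearrangementError(OligobandError):
    """A rearrangement description is invalid for the karyotype."""


class SimulationError(OligobandError):
    """Synthetic-data generation failed (e.g. placement retries exhausted)."""
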