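"""Exception hierarchy for the cargo-screen pipeline."""


class CpcargoError(Exception):
    """Base class for all package errors."""


class PatternSyntaxError(CpcargoError):
    """Malformed motif pattern text.

    Carries the 1-based column of the offending token.
    """

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


class SequenceError(CpcargoError):
    """A sequence contains letters outside the accepted amino-acid alphabet."""


class ProteomeError(CpcargoError):
    """Invalid FASTA input (empty file, duplicate accession, bad residues)."""


class AnnotationError(CpcargoError):
    """One or more malformed annotation rows; collects row-level messages."""

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.problems)
        super().__init__(f"{len(self.problems)} invalid annotation row(s): {lines}")


class InconsistentTopologyError(CpcargoError):
    """Terminus orientations contradict the membrane-crossing alternation."""


class AlignmentError(CpcargoError):
    """Invalid alignment request (unknown matrix, bad sequence)."""


class SimulationError(CpcargoError):
    """Infeasible simulation configuration (e.g. motif plan exceeds capacity)."""
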