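"""Exceptions shared across the pipeline."""


class MatemendError(Exception):
    """Base class for all pipeline errors."""


class NoUsablePairsError(MatemendError):
    """No mate pairs survived filtering; global statistics are undefined."""


class MissingContigError(MatemendError):
    """A contig named in one input is absent from another."""


class DegenerateModelError(MatemendError):
    """The null insert-size model has zero scale; posteriors are undefined."""


class SkippedContigError(MatemendError):
    """Contig is shorter than the minimum scannable size."""


class InvalidCallsError(MatemendError):
    """Misassembly calls overlap or are otherwise inconsistent."""


class UnsimulatableError(MatemendError):
    """Requested simulation geometry cannot accommodate the insert model."""
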