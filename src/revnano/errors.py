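"""Error conditions raised by the solver pipeline."""


class RevnanoError(Exception):
    """Base class for pipeline errors."""

    code = "E0"
    exit_code = 1


class InputError(RevnanoError):
    """Malformed or inconsistent sequence input."""

    code = "E1"
    exit_code = 1


class Stage2Error(RevnanoError):
    """E2: not enough staples placed after constraint propagation to
    perform reliable shortest-path calculations."""

    code = "E2"
    exit_code = 2


class OverlapError(RevnanoError):
    """E4: unresolvable staple-staple overlap (e.g. three staples claiming
    one scaffold base, or a trim that would erase a section)."""

    code = "E4"
    exit_code = 4
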