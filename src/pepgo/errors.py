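"""Exception hierarchy shared across the package.

Two broad failure classes are distinguished because the command-line
entry points map them to different exit codes: malformed or illegal
*input* (exit 2) versus violated *integrity* constraints discovered in
otherwise-parsable data (exit 3).
"""


class PepGoError(Exception):
    """Base class for all package-specific errors."""


class InputError(PepGoError):
    """Malformed input, illegal argument, or parse failure."""


class IntegrityError(PepGoError):
    """Structurally parsable data that violates an invariant
    (cycles, duplicate ids, orphan nodes, disjoint ontologies...)."""
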