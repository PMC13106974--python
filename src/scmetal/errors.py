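"""Exception hierarchy shared across the toolkit.

All user-facing failures derive from :class:`ScmetalError` so the CLI can
map them to exit code 2 (validation error) without catching unrelated bugs.
"""


class ScmetalError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ScmetalError):
    """A file is structurally wrong (missing column, bad header, unknown key)."""


class ValidationError(ScmetalError):
    """Parsed data violates an invariant (non-monotone time, bad window, ...)."""
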