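"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Malformed or inconsistent user input (reads, genome, parameters)."""


class DigestMismatchError(RuntimeError):
    """Archive was encoded against a different reference genome."""


class CorruptArchiveError(RuntimeError):
    """Archive bytes are truncated or fail to decode; names the block."""


class UnknownBackendError(KeyError):
    """Archive references a compression backend that is not registered."""
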