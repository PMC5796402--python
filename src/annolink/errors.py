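"""Exception hierarchy shared across the package."""


class AnnolinkError(Exception):
    """Base class for all package errors."""


class ContextError(AnnolinkError):
    """Malformed or unsupported JSON-LD context."""


class RegistryError(AnnolinkError):
    """Invalid registry configuration."""


class RoutingError(AnnolinkError):
    """No endpoint or endpoint chain can perform the requested translation."""

    def __init__(self, input_type: str, output_type: str, message: str | None = None):
        self.input_type = input_type
        self.output_type = output_type
        super().__init__(
            message
            or f"no registered endpoint converts <{input_type}> to <{output_type}>"
        )


class TransportError(AnnolinkError):
    """A fetcher failed to retrieve documents for a batch of IDs."""

    def __init__(self, endpoint_name: str, batch: list[str], cause: Exception | None = None):
        self.endpoint_name = endpoint_name
        self.batch = list(batch)
        self.cause = cause
        super().__init__(
            f"fetch failed on endpoint {endpoint_name!r} for batch of "
            f"{len(batch)} ID(s): {batch[:5]}{'...' if len(batch) > 5 else ''}"
        )
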