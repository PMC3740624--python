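"""MIRIAM registry: resource inference and identifiers.org URI round-trips.

A cross reference is a (namespace, identifier) pair. The bundled registry
snapshot gives each namespace an anchored identifier pattern, an
identifiers.org URI base and, where the community writes identifiers with a
literal prefix (``CHEBI:``, ``GO:``), that prefix — which lets a bare
numeric identifier be canonicalized and lets :func:`infer_resource` rank the
prefixed namespace first.

The snapshot is versioned and ships with the package; users may load their
own via :func:`load_registry`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional
from urllib.parse import unquote

__all__ = [
    "RegistryEntry",
    "Registry",
    "CrossReference",
    "RegistryError",
    "XrefValidationError",
    "UriParseError",
    "load_registry",
    "default_registry",
    "infer_resource",
    "to_uri",
    "from_uri",
]


class RegistryError(KeyError):
    """Unknown namespace."""


class XrefValidationError(ValueError):
    """Identifier fails its namespace pattern."""


class UriParseError(ValueError):
    """URI is not a recognizable identifiers.org / MIRIAM URN form."""


@dataclass(frozen=True)
class RegistryEntry:
    namespace: str
    display_name: str
    pattern: str
    uri_base: str
    id_prefix: Optional[str] = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.uri_base.endswith("/"):
            raise ValueError(f"{self.namespace}: uri_base must end with '/'")
        pat = self.pattern
        if not (pat.startswith("^") and pat.endswith("$")):
            raise ValueError(f"{self.namespace}: pattern must be anchored: {pat!r}")
        object.__setattr__(self, "_compiled", re.compile(pat))
        object.__setattr__(self, "aliases", tuple(self.aliases))

    def matches(self, identifier: str) -> bool:
        return bool(self._compiled.match(identifier))

    def canonicalize(self, identifier: str) -> str:
        """Insert the literal id_prefix when required and absent."""
        if self.matches(identifier):
            return identifier
        if self.id_prefix and self.matches(self.id_prefix + identifier):
            return self.id_prefix + identifier
        raise XrefValidationError(
            f"identifier {identifier!r} does not match pattern for "
            f"namespace {self.namespace!r}"
        )


class Registry:
    """Ordered collection of registry entries with alias resolution."""

    def __init__(self, entries: list[RegistryEntry], version: str = "unversioned"):
        self.version = version
        self.entries = list(entries)
        self._by_ns: dict[str, RegistryEntry] = {}
        for e in self.entries:
            self._by_ns[e.namespace] = e
            for alias in e.aliases:
                self._by_ns.setdefault(alias, e)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def get(self, namespace: str) -> RegistryEntry:
        try:
            return self._by_ns[namespace]
        except KeyError:
            raise RegistryError(f"unknown namespace {namespace!r}") from None

    def knows(self, namespace: str) -> bool:
        return namespace in self._by_ns


@dataclass(frozen=True)
class CrossReference:
    """A (namespace, identifier) pointer to an external database entry."""

    namespace: str
    identifier: str

    def validated(self, registry: Registry) -> "CrossReference":
        """Canonical form (prefix inserted, namespace de-aliased) or raise."""
        entry = registry.get(self.namespace)
        return CrossReference(entry.namespace, entry.canonicalize(self.identifier))

    def __str__(self) -> str:
        return f"{self.namespace}:{self.identifier}"


def load_registry(path) -> Registry:
    """Load a registry snapshot from a JSON file.

    Schema: ``{"version": str, "namespaces": [{namespace, display_name,
    pattern, uri_base, id_prefix?, aliases?}, ...]}``.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    entries = [
        RegistryEntry(
            namespace=ns["namespace"],
            display_name=ns.get("display_name", ns["namespace"]),
            pattern=ns["pattern"],
            uri_base=ns["uri_base"],
            id_prefix=ns.get("id_prefix"),
            aliases=tuple(ns.get("aliases", ())),
        )
        for ns in doc["namespaces"]
    ]
    return Registry(entries, version=doc.get("version", "unversioned"))


_DEFAULT: Optional[Registry] = None


def default_registry() -> Registry:
    """The snapshot bundled with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("gemannot.data").joinpath("registry.json")
        with resources.as_file(ref) as path:
            _DEFAULT = load_registry(path)
    return _DEFAULT


def infer_resource(identifier: str, registry: Registry | None = None) -> list[str]:
    """Namespaces whose identifier pattern matches ``identifier``.

    A namespace matches if the raw identifier fits its pattern, or if the
    identifier fits after inserting the namespace's literal id_prefix
    ("15422" matches chebi as "CHEBI:15422"). Namespaces whose literal
    prefix is present in the input come first; remaining candidates keep
    registry order. Empty list when nothing matches.
    """
    if not identifier:
        raise ValueError("identifier must be non-empty")
    registry = registry or default_registry()
    prefixed: list[str] = []
    rest: list[str] = []
    for entry in registry:
        direct = entry.matches(identifier)
        via_prefix = bool(
            entry.id_prefix and not direct and entry.matches(entry.id_prefix + identifier)
        )
        if not (direct or via_prefix):
            continue
        if entry.id_prefix and identifier.startswith(entry.id_prefix):
            prefixed.append(entry.namespace)
        else:
            rest.append(entry.namespace)
    return prefixed + rest


def to_uri(xref: CrossReference, registry: Registry | None = None) -> str:
    """identifiers.org URI for a cross reference (canonicalized)."""
    registry = registry or default_registry()
    entry = registry.get(xref.namespace)
    return entry.uri_base + entry.canonicalize(xref.identifier)


_URN_RE = re.compile(r"^urn:miriam:([^:]+):(.+)$")


def from_uri(uri: str, registry: Registry | None = None) -> CrossReference:
    """Parse an identifiers.org URI or legacy ``urn:miriam:`` form.

    Inverse of :func:`to_uri` on its range; legacy URNs may percent-encode
    colons inside the identifier and may use alias namespaces
    (``obo.chebi``), both of which are normalized away.
    """
    registry = registry or default_registry()
    m = _URN_RE.match(uri)
    if m:
        ns, ident = m.group(1), unquote(m.group(2))
        entry = registry.get(ns)  # raises RegistryError for unknown alias
        return CrossReference(entry.namespace, entry.canonicalize(ident))
    for scheme in ("https://identifiers.org/", "http://identifiers.org/"):
        if uri.startswith(scheme):
            tail = uri[len(scheme):]
            # namespace/identifier, identifier may itself contain ':' or '/'
            if "/" in tail:
                ns, ident = tail.split("/", 1)
            elif ":" in tail:  # compact form namespace:identifier
                ns, ident = tail.split(":", 1)
            else:
                raise UriParseError(f"cannot split namespace from {uri!r}")
            entry = registry.get(ns)
            return CrossReference(entry.namespace, entry.canonicalize(unquote(ident)))
    raise UriParseError(f"unrecognized cross-reference URI {uri!r}")
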