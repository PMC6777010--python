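"""Assay panel definitions and the amplified-gene query parser.

A *panel* is the set of genes a clinical NGS assay evaluates; genes off the
panel are unobserved.  The *query* is the comma-delimited list of genes a
clinical report calls amplified, entered exactly as printed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TextIO, Union

from .errors import PanelError, QueryError

__all__ = [
    "Panel",
    "AmplifiedQuery",
    "load_panel",
    "parse_amplified_list",
    "builtin_panels",
]

Source = Union[str, Path, TextIO]

#: Built-in panels shipped with the package, keyed by lowercase name.
#: "foundationone" is a 329-gene panel in the style of the widely used
#: Foundation One assay (see the packaged file header: the list is a
#: synthetic reconstruction, not the vendor's file).
_BUILTIN_FILES = {"foundationone": "foundationone.synthetic.txt"}


def builtin_panels() -> tuple[str, ...]:
    """Names of the packaged built-in panels."""
    return tuple(sorted(_BUILTIN_FILES))


@dataclass(frozen=True)
class Panel:
    """The set of gene symbols one assay evaluates.

    ``symbols`` preserves file order but is deduplicated case-insensitively
    (first occurrence wins); membership tests are case-insensitive.
    """

    name: str
    symbols: tuple[str, ...]
    _folded: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise PanelError(f"panel {self.name!r} has no genes")
        folded = frozenset(s.casefold() for s in self.symbols)
        if len(folded) != len(self.symbols):
            raise PanelError(f"panel {self.name!r} has duplicate symbols")
        object.__setattr__(self, "_folded", folded)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._folded

    def __len__(self) -> int:
        return len(self.symbols)

    def serialize(self) -> str:
        return "\n".join(self.symbols) + "\n"


@dataclass(frozen=True)
class AmplifiedQuery:
    """Ordered, deduplicated amplified-gene symbols plus the raw input."""

    symbols: tuple[str, ...]
    raw_text: str


def _parse_symbol_lines(stream: TextIO) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.casefold() not in seen:
            seen.add(line.casefold())
            out.append(line)
    return out


def load_panel(source: Source, name: str | None = None) -> Panel:
    """Load a panel from a file path, an open stream, or a built-in name.

    A string that is not an existing path is looked up among the built-in
    panels (case-insensitive); an unknown name raises a
    :class:`~ampinfer.errors.PanelError` listing the available built-ins.
    Panel files contain one symbol per line; blank lines and ``#`` comments
    are ignored; duplicates (case-insensitive) collapse.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_file():
            with open(path, encoding="utf-8") as fh:
                symbols = _parse_symbol_lines(fh)
            panel_name = name or path.stem
        else:
            key = str(source).casefold()
            if key not in _BUILTIN_FILES:
                raise PanelError(
                    f"unknown panel {source!r}: not a readable file and not a "
                    f"built-in (available built-ins: {', '.join(builtin_panels())})"
                )
            text = (
                resources.files("ampinfer") / "data" / _BUILTIN_FILES[key]
            ).read_text(encoding="utf-8")
            symbols = _parse_symbol_lines(io.StringIO(text))
            panel_name = key
    else:
        symbols = _parse_symbol_lines(source)
        panel_name = name or "custom"
    if not symbols:
        raise PanelError(f"panel {panel_name!r} has no genes")
    return Panel(name=panel_name, symbols=tuple(symbols))


def parse_amplified_list(text: str) -> AmplifiedQuery:
    """Parse a comma-delimited amplified-gene entry from a clinical report.

    Tokens are split on commas, stripped of surrounding whitespace, and
    deduplicated case-insensitively preserving first-occurrence order.
    An entry with no usable tokens raises a
    :class:`~ampinfer.errors.QueryError`.
    """
    tokens: list[str] = []
    seen: set[str] = set()
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if tok.casefold() not in seen:
            seen.add(tok.casefold())
            tokens.append(tok)
    if not tokens:
        raise QueryError("no gene names entered")
    return AmplifiedQuery(symbols=tuple(tokens), raw_text=text)
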