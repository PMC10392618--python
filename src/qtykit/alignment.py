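"""Annotated positional alignment of a native sequence and its QTY variant.

The QTY code is one-to-one at each position, so native and variant have
equal length and the "alignment" is an exact positional comparison — no
gaps, no alignment algorithm, no parameter ambiguity. Each fixed-width
block carries five tracks: a helix track marking TM columns, the native
line, a match line (``|`` identical, ``*`` substituted), the variant line,
and a right-edge coordinate ruler.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass

from .engine import QTYVariant


@dataclass(frozen=True)
class AlignmentBlock:
    start: int  # 1-based first column of the block
    helix: str
    native: str
    match: str
    variant: str

    @property
    def end(self) -> int:
        return self.start + len(self.native) - 1


@dataclass(frozen=True)
class AlignmentView:
    """Fixed-width text blocks of the native/variant comparison."""

    blocks: tuple[AlignmentBlock, ...]
    native_id: str = ""
    variant_id: str = ""

    def n_mismatches(self) -> int:
        return sum(b.match.count("*") for b in self.blocks)

    def to_text(self) -> str:
        name_w = max(len(self.native_id), len(self.variant_id), 6) + 2
        lines: list[str] = []
        for b in self.blocks:
            lines.append(" " * name_w + b.helix)
            lines.append(self.native_id.ljust(name_w) + b.native + f"  {b.end}")
            lines.append(" " * name_w + b.match)
            lines.append(self.variant_id.ljust(name_w) + b.variant + f"  {b.end}")
            lines.append("")
        return "\n".join(lines)

    def to_html(self) -> str:
        """Minimal HTML rendering: blue helix bars, red substitutions."""
        parts = ["<pre>"]
        for b in self.blocks:
            helix = b.helix.replace(
                "=", '<span style="color:blue">=</span>'
            )
            variant = "".join(
                f'<span style="color:red">{_html.escape(v)}</span>'
                if m == "*" else _html.escape(v)
                for v, m in zip(b.variant, b.match)
            )
            parts.append(helix)
            parts.append(_html.escape(b.native) + f"  {b.end}")
            parts.append(_html.escape(b.match))
            parts.append(variant + f"  {b.end}")
            parts.append("")
        parts.append("</pre>")
        return "\n".join(parts)


def render_pairwise(
    variant: QTYVariant, width: int = 60, mark_tm: bool = True
) -> AlignmentView:
    """Build the block view of *variant* against its native sequence.

    The helix track shows ``=`` under TM columns (blank when *mark_tm* is
    off); the count of ``*`` on the match lines equals the number of
    substitution events. Output is deterministic byte-for-byte.
    """
    if width < 10:
        raise ValueError(f"width must be at least 10, got {width}")
    native = variant.native.sequence
    var = variant.variant_sequence
    mask = variant.topology.membership(len(native))
    helix_full = "".join(
        "=" if (mark_tm and m) else " " for m in mask
    )
    match_full = "".join(
        "|" if a == b else "*" for a, b in zip(native, var)
    )
    blocks = []
    for off in range(0, len(native), width):
        sl = slice(off, off + width)
        blocks.append(
            AlignmentBlock(
                start=off + 1,
                helix=helix_full[sl],
                native=native[sl],
                match=match_full[sl],
                variant=var[sl],
            )
        )
    return AlignmentView(
        blocks=tuple(blocks),
        native_id=variant.native.id,
        variant_id=variant.variant_id,
    )
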