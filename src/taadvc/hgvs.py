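"""HGVS-lite protein-change parsing and formatting.

Only the small grammar needed for panel variant tables is supported —
three-letter amino-acid codes and the forms::

    p.Cys2663Ser                      missense
    p.Arg429*                         nonsense (stop gain)
    p.Ala39fs                         frameshift
    p.Lys1263del                      single-residue in-frame deletion
    p.Glu100_Lys102del[Seq]           multi-residue in-frame deletion
    p.Gly100_Pro101ins<Seq>           in-frame insertion

HGVS strings are trusted input: there is no transcript lookup and no
cDNA/protein consistency proof.  ``parse_protein_hgvs`` and
``format_protein_hgvs`` are mutually inverse on the supported grammar.
"""

from __future__ import annotations

import re

from .model import ChangeKind, ProteinChange

AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()
AA3_SET = frozenset(AA3)

_ONE_LETTER = dict(
    zip(AA3, "A R N D C Q E G H I L K M F P S T W Y V".split())
)


class HgvsParseError(ValueError):
    """Raised when a protein HGVS string falls outside the supported grammar."""


def one_letter(residue3: str) -> str:
    """Three-letter amino-acid code -> one-letter code."""
    try:
        return _ONE_LETTER[residue3]
    except KeyError:
        raise HgvsParseError(f"unknown amino-acid code {residue3!r}") from None


_RES_POS = r"(?P<ref>[A-Z][a-z]{2})(?P<pos>[1-9][0-9]*)"
_RES_POS2 = r"(?P<ref2>[A-Z][a-z]{2})(?P<pos2>[1-9][0-9]*)"

_SIMPLE = re.compile(rf"^{_RES_POS}(?P<rest>.+)$")
_RANGE = re.compile(rf"^{_RES_POS}_{_RES_POS2}(?P<op>del|ins)(?P<seq>[A-Za-z]*)$")


def _check_residue(code: str, text: str) -> str:
    if code not in AA3_SET:
        raise HgvsParseError(f"unknown amino-acid code {code!r} in {text!r}")
    return code


def _check_seq(seq: str, text: str) -> str:
    if len(seq) % 3:
        raise HgvsParseError(f"residue sequence {seq!r} in {text!r} is not 3-letter codes")
    for i in range(0, len(seq), 3):
        _check_residue(seq[i : i + 3], text)
    return seq


def parse_protein_hgvs(text: str) -> ProteinChange:
    """Parse a protein HGVS string into a :class:`ProteinChange`.

    Raises :class:`HgvsParseError` naming the offending token for anything
    outside the supported grammar.
    """
    if not text:
        raise HgvsParseError("empty protein HGVS string")
    if not text.startswith("p."):
        raise HgvsParseError(f"{text!r} does not start with 'p.'")
    body = text[2:].replace(" ", "")
    if not body:
        raise HgvsParseError(f"{text!r} has no change after 'p.'")

    m = _RANGE.match(body)
    if m:
        ref = _check_residue(m["ref"], text)
        ref2 = _check_residue(m["ref2"], text)
        pos, pos2 = int(m["pos"]), int(m["pos2"])
        seq = _check_seq(m["seq"], text) or None
        if m["op"] == "ins":
            if pos2 != pos + 1:
                raise HgvsParseError(
                    f"insertion anchors must be adjacent residues in {text!r}"
                )
            if seq is None:
                raise HgvsParseError(f"insertion without inserted residues in {text!r}")
            kind = ChangeKind.INFRAME_INS
        else:
            kind = ChangeKind.INFRAME_DEL
        return ProteinChange(
            kind=kind,
            ref_residue=ref,
            position=pos,
            span_end=pos2,
            span_end_residue=ref2,
            seq=seq,
        )

    m = _SIMPLE.match(body)
    if not m:
        raise HgvsParseError(f"unsupported protein change {text!r}")
    ref = _check_residue(m["ref"], text)
    pos = int(m["pos"])
    rest = m["rest"]
    if rest in ("*", "Ter"):
        return ProteinChange(ChangeKind.NONSENSE, ref, pos, alt_residue="*")
    if rest == "fs":
        return ProteinChange(ChangeKind.FRAMESHIFT, ref, pos)
    if rest == "del":
        return ProteinChange(ChangeKind.INFRAME_DEL, ref, pos)
    if rest in AA3_SET:
        if rest == ref:
            raise HgvsParseError(f"silent change {text!r} is not a protein change")
        return ProteinChange(ChangeKind.MISSENSE, ref, pos, alt_residue=rest)
    raise HgvsParseError(f"unsupported token {rest!r} in {text!r}")


def format_protein_hgvs(change: ProteinChange) -> str:
    """Render a :class:`ProteinChange` back to its HGVS-lite string."""
    ref, pos = change.ref_residue, change.position
    if change.kind is ChangeKind.MISSENSE:
        return f"p.{ref}{pos}{change.alt_residue}"
    if change.kind is ChangeKind.NONSENSE:
        return f"p.{ref}{pos}*"
    if change.kind is ChangeKind.FRAMESHIFT:
        return f"p.{ref}{pos}fs"
    if change.kind is ChangeKind.INFRAME_DEL:
        if change.span_end == pos and change.span_end_residue is None:
            return f"p.{ref}{pos}del"
        return (
            f"p.{ref}{pos}_{change.span_end_residue}{change.span_end}del"
            f"{change.seq or ''}"
        )
    if change.kind is ChangeKind.INFRAME_INS:
        return (
            f"p.{ref}{pos}_{change.span_end_residue}{change.span_end}ins{change.seq}"
        )
    raise ValueError(f"unknown change kind {change.kind}")
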