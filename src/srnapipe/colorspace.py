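"""SOLiD colorspace (csfasta) encoding and decoding.

Each color encodes a dinucleotide transition under the standard dibase
code: with the 2-bit assignment A=0, C=1, G=2, T=3 the color of a
dinucleotide is the XOR of the two base codes, which reproduces the
canonical table (0: AA/CC/GG/TT, 1: AC/CA/GT/TG, 2: AG/GA/CT/TC,
3: AT/TA/CG/GC).  A read is a primer base followed by the color string;
decoding walks the transitions forward from the primer.
"""

from __future__ import annotations

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"


class ColorspaceError(ValueError):
    pass


def encode(seq: str, primer: str = "T") -> str:
    """Encode a DNA sequence as colors, starting from the primer base."""
    seq = seq.upper().replace("U", "T")
    prev = primer.upper()
    if prev not in _CODE:
        raise ColorspaceError(f"invalid primer base {primer!r}")
    colors = []
    for b in seq:
        if b not in _CODE:
            raise ColorspaceError(f"invalid base {b!r}")
        colors.append(str(_CODE[prev] ^ _CODE[b]))
        prev = b
    return "".join(colors)


def decode(primer: str, colors: str) -> str:
    """Decode colors into bases; the returned string excludes the primer."""
    prev = primer.upper()
    if prev not in _CODE:
        raise ColorspaceError(f"invalid primer base {primer!r}")
    code = _CODE[prev]
    out = []
    for c in colors:
        if c not in "0123":
            raise ColorspaceError(f"invalid color symbol {c!r}")
        code ^= int(c)
        out.append(_BASE[code])
    return "".join(out)


def read_csfasta(path) -> list[tuple[str, str, str]]:
    """Yield (id, primer_base, colors) records from a csfasta file."""
    records = []
    rid = None
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if ln.startswith(">"):
                rid = ln[1:].split()[0]
            else:
                if rid is None:
                    raise ColorspaceError(f"{path}: color line before header")
                records.append((rid, ln[0], ln[1:]))
                rid = None
    return records


def write_csfasta(records: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, primer, colors in records:
            fh.write(f">{rid}\n{primer}{colors}\n")
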