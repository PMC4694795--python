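"""Region taxonomy of mature-tRNA fragments.

A mature tRNA of templated length ``L`` carries the nontemplated CCA tail at
mature positions ``L+1..L+3``.  Fragments are classified into three regions by
their endpoints in mature coordinates (1-based, +1 = first nucleotide):

* ``3p`` — the 3' terminus coincides with any base of the CCA tail;
* ``5p`` — the 5' terminus is exactly position +1 (and the fragment does not
  reach the CCA);
* ``i``  — wholly internal: starts at position >= 2 and ends strictly before
  the first C of the CCA.

The CCA rule is checked first, so a (pathological) full-span fragment that both
starts at +1 and ends inside the CCA is reported as ``3p``.
"""

from __future__ import annotations

REGIONS = ("5p", "i", "3p")

#: Sort key used when ordering fragments for display (5' -> internal -> 3').
REGION_ORDER = {r: i for i, r in enumerate(REGIONS)}


def classify_region(frag_start: int, frag_end: int, L: int) -> str:
    """Classify a fragment of a mature tRNA into ``{"5p", "i", "3p"}``.

    Parameters
    ----------
    frag_start, frag_end
        Fragment endpoints in mature coordinates, 1-based inclusive.
    L
        Templated (spliced, CCA-less) length of the mature tRNA.

    Raises
    ------
    ValueError
        If the coordinates do not satisfy ``1 <= frag_start <= frag_end <= L+3``.
    """
    if L < 1:
        raise ValueError(f"templated length must be positive, got {L}")
    if not (1 <= frag_start <= frag_end <= L + 3):
        raise ValueError(
            f"fragment ({frag_start}, {frag_end}) out of range for mature tRNA "
            f"of templated length {L} (valid span 1..{L + 3})"
        )
    if frag_end > L:
        return "3p"
    if frag_start == 1:
        return "5p"
    return "i"


def is_full_span(frag_start: int, frag_end: int, L: int) -> bool:
    """True for a fragment that starts at +1 *and* ends inside the CCA tail."""
    return frag_start == 1 and frag_end > L
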