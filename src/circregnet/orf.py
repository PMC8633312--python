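"""Open reading frames on circular sequences, including ORFs that cross
the back-splice junction.

A circle of length L is scanned as its doubled sequence (seq + seq): every
ATG starting below L is walked in-frame to its first stop codon.  An ORF
whose end runs past L crosses the junction (``crosses_bsj``).  Reading is
capped at two laps — a reading frame with no stop at all (a potential
rolling-circle frame) is reported at the maximal scanned length with
``no_stop`` set rather than extended indefinitely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

_STOPS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGT")


@dataclass(frozen=True)
class CircularORF:
    circ_id: str
    start: int            # 0-based offset on the circle
    length_nt: int        # multiple of 3, includes the stop codon if any
    frame: int            # start % 3
    crosses_bsj: bool
    no_stop: bool = False

    @property
    def peptide_length_aa(self) -> int:
        return self.length_nt // 3 - (0 if self.no_stop else 1)


def find_circular_orfs(
    sequence: str,
    min_len_nt: int = 150,
    circ_id: str = "",
    longest_only: bool = False,
) -> list[CircularORF]:
    """Enumerate ATG-initiated ORFs on a circle via the doubled sequence.

    All ATG starts are reported by default; with ``longest_only`` only the
    5'-most start per (frame, stop) run is kept.
    """
    seq = sequence.upper().replace("U", "T")
    L = len(seq)
    if L < 3:
        raise ValueError("circular sequence must be >= 3 nt")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    doubled = seq + seq

    orfs: list[CircularORF] = []
    used_stops: set[tuple[int, int]] = set()   # (frame, stop index) seen
    for start in range(L):
        if doubled[start:start + 3] != "ATG":
            continue
        j = start
        stop_at = None
        while j + 3 <= 2 * L:
            codon = doubled[j:j + 3]
            if codon in _STOPS:
                stop_at = j
                break
            j += 3
        if stop_at is not None:
            length = stop_at + 3 - start
            no_stop = False
        else:
            length = ((2 * L - start) // 3) * 3
            no_stop = True
        if length < min_len_nt:
            continue
        if longest_only:
            key = (start % 3, stop_at if stop_at is not None else -1)
            if key in used_stops:
                continue
            used_stops.add(key)
        orfs.append(
            CircularORF(
                circ_id=circ_id,
                start=start,
                length_nt=length,
                frame=start % 3,
                crosses_bsj=start + length > L,
                no_stop=no_stop,
            )
        )
    return orfs


def find_orfs_per_circle(
    sequences: Mapping[str, str], min_len_nt: int = 150
) -> dict[str, list[CircularORF]]:
    return {
        cid: find_circular_orfs(seq, min_len_nt=min_len_nt, circ_id=cid)
        for cid, seq in sequences.items()
    }


# ---------------------------------------------------------------------------
# coding potential accounting
# ---------------------------------------------------------------------------

@dataclass
class CodingPotentialCall:
    circ_id: str
    has_orf: bool
    has_bsj_orf: bool
    has_ires: bool
    potential: bool       # has_ires AND has_orf


def coding_potential(
    orfs_per_circle: Mapping[str, Iterable[CircularORF]],
    ires_flags: Mapping[str, bool],
    min_len_nt: int = 150,
    circ_classes: Mapping[str, str] | None = None,
) -> tuple[list[CodingPotentialCall], dict]:
    """Combine ORF evidence with externally supplied IRES flags.

    Circles with ORFs but no IRES record are treated as has_ires = False
    (with a warning); the returned accounting gives the Venn-style counts
    (ORF only, IRES only, both, both with a junction-crossing ORF), overall
    and stratified by circRNA class when classes are supplied.
    """
    import warnings

    circ_ids = sorted(set(orfs_per_circle) | set(ires_flags))
    missing = [c for c in orfs_per_circle if c not in ires_flags]
    if missing:
        warnings.warn(
            f"{len(missing)} circle(s) have ORF records but no IRES flag; "
            "treating as has_ires=False"
        )

    calls = []
    for cid in circ_ids:
        qualifying = [
            o for o in orfs_per_circle.get(cid, []) if o.length_nt >= min_len_nt
        ]
        has_orf = bool(qualifying)
        has_bsj = any(o.crosses_bsj for o in qualifying)
        has_ires = bool(ires_flags.get(cid, False))
        calls.append(
            CodingPotentialCall(cid, has_orf, has_bsj, has_ires,
                                has_ires and has_orf)
        )

    def _counts(subset: list[CodingPotentialCall]) -> dict[str, int]:
        return {
            "n": len(subset),
            "orf": sum(c.has_orf for c in subset),
            "bsj_orf": sum(c.has_bsj_orf for c in subset),
            "ires": sum(c.has_ires for c in subset),
            "orf_only": sum(c.has_orf and not c.has_ires for c in subset),
            "ires_only": sum(c.has_ires and not c.has_orf for c in subset),
            "both": sum(c.potential for c in subset),
            "both_bsj": sum(c.potential and c.has_bsj_orf for c in subset),
            "neither": sum(not c.has_orf and not c.has_ires for c in subset),
        }

    accounting: dict = _counts(calls)
    if circ_classes:
        accounting["by_class"] = {
            cls: _counts([c for c in calls if circ_classes.get(c.circ_id) == cls])
            for cls in sorted(set(circ_classes.values()))
        }
    return calls, accounting
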