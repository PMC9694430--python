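"""Expression-construct enumeration and protein mass prediction.

Soluble bacterial expression of a eukaryotic kinase domain usually requires
trying several boundary variants: the annotated domain is extended or trimmed
at the N- and C-termini by small offsets, and each variant is cloned behind a
cleavable purification tag.  This module enumerates those variants and
computes the tagged and TEV-cleaved protein sequences together with their
average-isotopic molecular weights, which is what one compares against an
SDS-PAGE band or a deconvoluted intact-mass spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .errors import MalformedInputError, MalformedSequenceError

#: N-terminal His6 + TEV-site tag added by the expression vector.  TEV
#: protease cuts after the Q of ENLYFQ, leaving an SM- scar on the protein.
HIS_TEV_TAG = "MHHHHHHSSGVDLGTENLYFQSM"
TEV_REMNANT = "SM"

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise MalformedSequenceError("empty protein sequence")
    for pos, residue in enumerate(seq, start=1):
        if residue not in _VALID_RESIDUES:
            raise MalformedSequenceError(f"invalid residue {residue!r} at position {pos}")


@dataclass(frozen=True)
class ConstructDesign:
    """One kinase-domain boundary variant with tagged/cleaved sequences."""

    gene: str
    construct_id: str
    start_res: int
    end_res: int
    construct_seq: str
    tagged_seq: str
    cleaved_seq: str
    mw_tagged: float
    mw_cleaved: float


def enumerate_boundaries(
    domain_start: int,
    domain_end: int,
    n_offsets: Sequence[int],
    c_offsets: Sequence[int],
    protein_length: int,
) -> list[tuple[int, int]]:
    """Cartesian product of N/C offsets applied to the annotated domain.

    Residue positions are 1-based inclusive and clipped to
    ``[1, protein_length]``; duplicates after clipping are removed keeping
    the first occurrence; ordering is by N offset then C offset.  Variants
    whose start exceeds their end after offsetting are dropped.
    """
    if not (1 <= domain_start <= domain_end <= protein_length):
        raise MalformedInputError(
            f"invalid domain [{domain_start}, {domain_end}] for length {protein_length}"
        )
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    for n_off in n_offsets:
        for c_off in c_offsets:
            start = min(max(domain_start + int(n_off), 1), protein_length)
            end = min(max(domain_end + int(c_off), 1), protein_length)
            if start > end:
                continue
            if (start, end) not in seen:
                seen.add((start, end))
                out.append((start, end))
    return out


def build_tagged(construct_seq: str) -> tuple[str, str]:
    """Return ``(tagged_seq, cleaved_seq)`` for a kinase-domain sequence."""
    _validate_sequence(construct_seq)
    return HIS_TEV_TAG + construct_seq, TEV_REMNANT + construct_seq


def predict_mw(protein_seq: str, monoisotopic: bool = False) -> float:
    """Molecular weight in Daltons (average isotopic unless requested).

    Sum of residue masses plus one water, as for any linear polypeptide.
    """
    _validate_sequence(protein_seq)
    return float(molecular_weight(protein_seq, seq_type="protein", monoisotopic=monoisotopic))


def design_constructs(
    sequences: Mapping[str, str],
    domains: Iterable[tuple[str, int, int]],
    n_offsets: Sequence[int] = (-10, 0),
    c_offsets: Sequence[int] = (0, 10),
    monoisotopic: bool = False,
) -> list[ConstructDesign]:
    """Enumerate boundary variants for every gene with a domain annotation.

    ``sequences`` maps locus id to the full-length protein sequence;
    ``domains`` yields ``(locus_id, domain_start, domain_end)`` rows.
    """
    designs: list[ConstructDesign] = []
    for locus_id, dstart, dend in domains:
        seq = sequences.get(locus_id)
        if seq is None:
            raise MalformedInputError(f"no sequence for {locus_id}")
        _validate_sequence(seq)
        for i, (start, end) in enumerate(
            enumerate_boundaries(dstart, dend, n_offsets, c_offsets, len(seq)), start=1
        ):
            construct_seq = seq[start - 1 : end]
            tagged, cleaved = build_tagged(construct_seq)
            designs.append(
                ConstructDesign(
                    gene=locus_id,
                    construct_id=f"{locus_id}-c{i:03d}",
                    start_res=start,
                    end_res=end,
                    construct_seq=construct_seq,
                    tagged_seq=tagged,
                    cleaved_seq=cleaved,
                    mw_tagged=predict_mw(tagged, monoisotopic),
                    mw_cleaved=predict_mw(cleaved, monoisotopic),
                )
            )
    return designs


def constructs_table(designs: Sequence[ConstructDesign]) -> pd.DataFrame:
    """Tabular view of a construct set (masses reported to 2 decimals)."""
    return pd.DataFrame(
        [
            {
                "locus_id": d.gene,
                "construct_id": d.construct_id,
                "start_res": d.start_res,
                "end_res": d.end_res,
                "mw_tagged": round(d.mw_tagged, 2),
                "mw_cleaved": round(d.mw_cleaved, 2),
            }
            for d in designs
        ]
    )
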