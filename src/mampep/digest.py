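"""Protein chains and in-silico tryptic digestion.

Trypsin specificity: cleave C-terminal to K or R, never when the next residue
is proline; the chain termini count as canonical cleavage points. Coordinates
are 1-based inclusive throughout, matching the site labels used for antibody
attributes (M255, N300, K450, ...).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from pyteomics import fasta as _fasta

from .constants import residue_compositions

STANDARD_RESIDUES = frozenset(residue_compositions().keys())


@dataclass(frozen=True)
class ProteinChain:
    id: str
    sequence: str
    role: str = "other"  # heavy | light | other

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.id!r}: empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(f"chain {self.id!r}: unknown residue {aa!r} at position {i}")
        if self.role not in ("heavy", "light", "other"):
            raise ValueError(f"chain {self.id!r}: invalid role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageRule:
    cleave_after: frozenset[str] = frozenset({"K", "R"})
    suppress_before: frozenset[str] = frozenset({"P"})

    def cleavage_points(self, sequence: str) -> list[int]:
        """Internal cut points: cut after 1-based position i (i < len)."""
        points = []
        for i in range(1, len(sequence)):
            if sequence[i - 1] in self.cleave_after and sequence[i] not in self.suppress_before:
                points.append(i)
        return points


TRYPSIN = CleavageRule()


@dataclass(frozen=True)
class Peptide:
    """A chain substring with 1-based inclusive coordinates."""

    chain_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    specific: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid peptide coordinates {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("peptide sequence length does not match coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    def spans(self, position: int) -> bool:
        return self.start <= position <= self.end


def digest(chain: ProteinChain, rule: CleavageRule = TRYPSIN, max_missed: int = 1,
           min_len: int = 1) -> list[Peptide]:
    """All fully-specific peptides with 0..max_missed missed cleavages.

    Peptides with ``m`` missed cleavages are unions of ``m + 1`` consecutive
    fully-cleaved fragments. Ordered by (start, end). ``min_len`` drops short
    fragments from the output (their residues may then be uncovered).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = chain.sequence
    points = rule.cleavage_points(seq)
    bounds = [0] + points + [len(seq)]  # fragment k spans bounds[k]..bounds[k+1]-1 (0-based)
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m
            if j >= n_frag:
                break
            start0, end0 = bounds[i], bounds[j + 1]
            if end0 - start0 < min_len:
                continue
            peptides.append(Peptide(
                chain_id=chain.id,
                start=start0 + 1,
                end=end0,
                sequence=seq[start0:end0],
                missed_cleavages=m,
            ))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def enumerate_semi_specific(chain: ProteinChain, rule: CleavageRule = TRYPSIN,
                            min_len: int = 1, max_len: int = 50) -> list[Peptide]:
    """Semi-tryptic peptides: exactly one terminus at a canonical cleavage point.

    Chain termini count as canonical. Fully-specific peptides are excluded;
    the results are flagged ``specific=False`` and exist to classify observed
    components when computing the non-specific cleavage rate.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    seq = chain.sequence
    canonical = {0, len(seq)} | set(rule.cleavage_points(seq))
    internal = sorted(rule.cleavage_points(seq))
    out = []
    for s0 in range(len(seq)):
        for e0 in range(s0 + min_len, min(s0 + max_len, len(seq)) + 1):
            n_canon = (s0 in canonical) + (e0 in canonical)
            if n_canon != 1:
                continue
            missed = sum(1 for p in internal if s0 < p < e0)
            out.append(Peptide(
                chain_id=chain.id, start=s0 + 1, end=e0,
                sequence=seq[s0:e0], missed_cleavages=missed, specific=False,
            ))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def read_fasta(path: str | Path, roles: dict[str, str] | None = None) -> list[ProteinChain]:
    """Read protein chains from FASTA; roles inferred from HC/LC header tokens.

    ``roles`` overrides inference, mapping chain id -> heavy|light|other.
    """
    chains = []
    for header, seq in _fasta.read(str(path)):
        chain_id = header.split()[0]
        tokens = {t.upper().strip(",;") for t in header.replace("|", " ").split()}
        if roles and chain_id in roles:
            role = roles[chain_id]
        elif tokens & {"HC", "HEAVY"}:
            role = "heavy"
        elif tokens & {"LC", "LIGHT"}:
            role = "light"
        else:
            role = "other"
        chains.append(ProteinChain(id=chain_id, sequence=seq.strip("*"), role=role))
    if not chains:
        raise ValueError(f"no sequences found in {path}")
    return chains
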