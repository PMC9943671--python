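"""Circular DNAzyme probe design against target RNAs.

A circular DNAzyme probe carries, around one covalently closed circle, two
recognition arms (20 nt each) complementary to the target RNA on either side
of a purine–pyrimidine dinucleotide, a catalytic core (by default the
canonical 10–23 DNAzyme core) positioned at the junction, a 20-nt reference
region bound by the reference fluorescent probe on every amplicon repeat, and
a barcode anchor for branched-barcode hybridization.  Upon hybridization the
core cleaves the RNA at the R–Y junction; after dephosphorylation the
upstream cleavage product primes rolling circle amplification on the probe
itself (RNA-primed RCA), so no exogenous primer — and none of its nonspecific
amplification — is needed.

Coordinates are 0-based with half-open windows; positions on the circle are
taken modulo the circle length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import gc_fraction

__all__ = [
    "TargetTranscript",
    "CleavageSite",
    "CircularDNAzymeProbe",
    "ProbeDesignConfig",
    "ProbeDesignError",
    "DEFAULT_CATALYTIC_CORE",
    "find_cleavage_sites",
    "rank_cleavage_sites",
    "design_circular_dnazyme",
    "make_control_variant",
    "screen_specificity",
    "emit_padlock_linker",
    "orthogonal_sequences",
    "read_targets_fasta",
    "probe_sheet",
    "write_padlock_fasta",
]

# canonical 10-23 DNAzyme catalytic core, 5'->3'
DEFAULT_CATALYTIC_CORE = "GGCTAGCTACAACGA"

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("UC")

# 10-23 junction preference: AU > GU > AC > GC
DEFAULT_SITE_PREFERENCE = ("AU", "GU", "AC", "GC")


class ProbeDesignError(ValueError):
    """Raised when a probe cannot be designed from the given inputs."""


def _clean_rna(sequence: str, label: str = "sequence") -> str:
    seq = sequence.strip().upper().replace(" ", "")
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    if "T" in seq:
        warnings.warn(
            f"{label}: DNA-style 'T' found in RNA input; converting T->U",
            stacklevel=3,
        )
        seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{label}: invalid RNA characters {sorted(bad)}")
    return seq


def revcomp_dna(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def rna_window_to_arm(window_rna: str) -> str:
    """DNA arm (5'->3') complementary to an RNA target window (5'->3')."""
    return str(Seq(window_rna).back_transcribe().reverse_complement())


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass(frozen=True)
class TargetTranscript:
    """A target RNA, 5'->3', over {A,C,G,U}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_rna(self.sequence, self.id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageSite:
    """A purine–pyrimidine junction cleavable by the 10-23 DNAzyme.

    ``position`` indexes the purine of the dinucleotide (0-based); cleavage
    occurs between ``position`` and ``position + 1``.
    """

    position: int
    dinucleotide: str
    flank_ok: bool

    def __post_init__(self) -> None:
        if len(self.dinucleotide) != 2:
            raise ValueError("dinucleotide must have length 2")
        if self.dinucleotide[0] not in PURINES or self.dinucleotide[1] not in PYRIMIDINES:
            raise ValueError(f"not a purine-pyrimidine junction: {self.dinucleotide}")


@dataclass
class ProbeDesignConfig:
    arm_len: int = 20
    reference_len: int = 20
    anchor_len: int = 20
    catalytic_core: str = DEFAULT_CATALYTIC_CORE
    spacer: str = "TT"
    site_preference: tuple[str, ...] = DEFAULT_SITE_PREFERENCE
    critical_window: int = 8  # nt on each side of the junction
    seed: int = 0


@dataclass(frozen=True)
class CircularDNAzymeProbe:
    """One designed circular probe and its provenance.

    ``arm_5p`` hybridizes the target region downstream (3') of the cleavage
    junction, ``arm_3p`` the upstream region — arms and target anneal
    antiparallel, so the probe's 5' arm faces the target's 3' flank.
    ``recognition_rna`` is the 2*arm_len target-sense window the arms cover;
    the junction sits between its indices ``arm_len - 1`` and ``arm_len``.
    """

    target_id: str
    arm_5p: str
    arm_3p: str
    catalytic_core: str
    reference_region: str
    barcode_anchor: str
    spacer: str
    circle_sequence: str
    kind: str  # matched | SNV | MM12 | random | core_deleted
    site: CleavageSite | None = None
    recognition_rna: str | None = None

    @property
    def arm_len(self) -> int:
        return len(self.arm_5p)

    def circle_position(self, i: int) -> int:
        return i % len(self.circle_sequence)


def find_cleavage_sites(transcript: TargetTranscript, arm_len: int = 20) -> list[CleavageSite]:
    """All R–Y dinucleotide junctions in a transcript, sorted by position.

    ``flank_ok`` is true iff at least ``arm_len`` nucleotides are available
    on each side of the junction (the purine counts toward the upstream
    flank).
    """
    if arm_len < 1:
        raise ValueError("arm_len must be >= 1")
    seq = transcript.sequence
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] in PURINES and seq[i + 1] in PYRIMIDINES:
            upstream = i + 1
            downstream = len(seq) - i - 1
            sites.append(
                CleavageSite(
                    position=i,
                    dinucleotide=seq[i : i + 2],
                    flank_ok=(upstream >= arm_len and downstream >= arm_len),
                )
            )
    return sites


def rank_cleavage_sites(
    sites: list[CleavageSite],
    preference: tuple[str, ...] = DEFAULT_SITE_PREFERENCE,
) -> list[CleavageSite]:
    """Usable sites first, ordered by dinucleotide preference then position."""
    order = {d: i for i, d in enumerate(preference)}

    def key(s: CleavageSite):
        return (not s.flank_ok, order.get(s.dinucleotide, len(order)), s.position)

    return sorted(sites, key=key)


def orthogonal_sequences(
    n: int,
    length: int,
    forbidden_kmers: set[str] | None = None,
    rng: np.random.Generator | None = None,
    gc_bounds: tuple[float, float] = (0.4, 0.6),
    max_homopolymer: int = 4,
    k: int = 10,
    max_tries: int = 100_000,
) -> list[str]:
    """Rejection-sample mutually orthogonal DNA sequences.

    Constraints: GC fraction within ``gc_bounds``, no homopolymer run longer
    than ``max_homopolymer``, and no ``k``-mer shared with ``forbidden_kmers``
    or with previously accepted sequences (both strands are excluded).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    forbidden = set(forbidden_kmers or ())
    bases = np.array(list("ACGT"))
    out: list[str] = []
    for _ in range(max_tries):
        if len(out) == n:
            break
        cand = "".join(rng.choice(bases, size=length))
        lo, hi = gc_bounds
        if not (lo <= gc_fraction(cand) <= hi):
            continue
        if _max_homopolymer(cand) > max_homopolymer:
            continue
        cand_kmers = _kmers(cand, k) | _kmers(revcomp_dna(cand), k)
        if cand_kmers & forbidden:
            continue
        out.append(cand)
        forbidden |= cand_kmers
    if len(out) < n:
        raise ProbeDesignError("could not sample enough orthogonal sequences")
    return out


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def design_circular_dnazyme(
    transcript: TargetTranscript,
    site: CleavageSite,
    config: ProbeDesignConfig | None = None,
) -> CircularDNAzymeProbe:
    """Design the matched circular probe for one cleavage site.

    The circle (5'->3') is arm_5p + core + arm_3p + spacer + reference +
    spacer + anchor + spacer; reference region and barcode anchor come from a
    seeded orthogonal-sequence pool that avoids any 10-mer of the target.
    """
    config = config or ProbeDesignConfig()
    L = config.arm_len
    if not site.flank_ok:
        raise ProbeDesignError(
            f"site at {site.position} lacks {L} nt of flank on both sides"
        )
    seq = transcript.sequence
    upstream = seq[site.position + 1 - L : site.position + 1]
    downstream = seq[site.position + 1 : site.position + 1 + L]
    arm_5p = rna_window_to_arm(downstream)
    arm_3p = rna_window_to_arm(upstream)

    target_dna = seq.replace("U", "T")
    forbidden = _kmers(target_dna, 10) | _kmers(revcomp_dna(target_dna), 10)
    rng = np.random.default_rng(config.seed)
    reference_region, barcode_anchor = orthogonal_sequences(
        2,
        max(config.reference_len, config.anchor_len),
        forbidden_kmers=forbidden,
        rng=rng,
    )
    reference_region = reference_region[: config.reference_len]
    barcode_anchor = barcode_anchor[: config.anchor_len]

    sp = config.spacer
    circle = (
        arm_5p
        + config.catalytic_core
        + arm_3p
        + sp
        + reference_region
        + sp
        + barcode_anchor
        + sp
    )
    return CircularDNAzymeProbe(
        target_id=transcript.id,
        arm_5p=arm_5p,
        arm_3p=arm_3p,
        catalytic_core=config.catalytic_core,
        reference_region=reference_region,
        barcode_anchor=barcode_anchor,
        spacer=sp,
        circle_sequence=circle,
        kind="matched",
        site=site,
        recognition_rna=upstream + downstream,
    )


def _mutate_positions(seq: str, positions, rng: np.random.Generator, alphabet: str) -> str:
    out = list(seq)
    others = {b: [a for a in alphabet if a != b] for b in alphabet}
    for p in positions:
        out[p] = others[out[p]][rng.integers(len(others[out[p]]))]
    return "".join(out)


def _even_positions(start: int, length: int, n: int) -> list[int]:
    # n positions spread evenly over [start, start+length)
    pos = [start + int(np.floor((i + 0.5) * length / n)) for i in range(n)]
    if len(set(pos)) != n:
        raise ProbeDesignError("region too short to spread mismatches evenly")
    return pos


def _random_region(
    original: str, rng: np.random.Generator, alphabet: str, max_tries: int = 100_000
) -> str:
    """Same length and GC (+-5%), sharing no 10-mer with the original."""
    target_kmers = _kmers(original, 10)
    gc_letters = set("GC")
    gc0 = sum(c in gc_letters for c in original) / len(original)
    letters = np.array(list(alphabet))
    for _ in range(max_tries):
        cand = "".join(rng.choice(letters, size=len(original)))
        gc = sum(c in gc_letters for c in cand) / len(cand)
        if abs(gc - gc0) > 0.05:
            continue
        if len(original) >= 10 and _kmers(cand, 10) & target_kmers:
            continue
        return cand
    raise ProbeDesignError("could not sample a random control region")


def make_control_variant(subject, kind: str, seed: int = 0, region: tuple[int, int] | None = None):
    """Generate a negative-control variant of a transcript or probe.

    Transcript controls mutate the recognition region of the RNA substrate
    (default: the whole sequence): ``SNV`` places a single substitution at
    the central position, ``MM12`` places exactly 12 substitutions spread
    evenly, ``random`` replaces the region with a GC-matched sequence sharing
    no 10-mer with the original.  Probe controls mutate the recognition arms
    the same way, or replace the catalytic core with an inert spacer of equal
    length (``core_deleted``).
    """
    rng = np.random.default_rng(seed)
    if isinstance(subject, TargetTranscript):
        seq = subject.sequence
        start, end = region if region is not None else (0, len(seq))
        reg = seq[start:end]
        if kind == "SNV":
            mutated = _mutate_positions(seq, [start + len(reg) // 2], rng, "ACGU")
        elif kind == "MM12":
            if len(reg) < 12:
                raise ProbeDesignError("recognition region shorter than 12 nt")
            mutated = _mutate_positions(seq, _even_positions(start, len(reg), 12), rng, "ACGU")
        elif kind == "random":
            mutated = seq[:start] + _random_region(reg, rng, "ACGU") + seq[end:]
        else:
            raise ValueError(f"unknown transcript control kind: {kind}")
        return TargetTranscript(id=f"{subject.id}_{kind}", sequence=mutated)

    if isinstance(subject, CircularDNAzymeProbe):
        arms = subject.arm_5p + subject.arm_3p
        if kind == "core_deleted":
            inert = ("TTC" * len(subject.catalytic_core))[: len(subject.catalytic_core)]
            return _rebuild_probe(subject, subject.arm_5p, subject.arm_3p, core=inert, kind=kind)
        if kind == "SNV":
            mutated = _mutate_positions(arms, [len(arms) // 2], rng, "ACGT")
        elif kind == "MM12":
            if len(arms) < 12:
                raise ProbeDesignError("recognition arms shorter than 12 nt")
            mutated = _mutate_positions(arms, _even_positions(0, len(arms), 12), rng, "ACGT")
        elif kind == "random":
            mutated = _random_region(arms, rng, "ACGT")
        else:
            raise ValueError(f"unknown probe control kind: {kind}")
        n5 = len(subject.arm_5p)
        return _rebuild_probe(subject, mutated[:n5], mutated[n5:], core=subject.catalytic_core, kind=kind)

    raise TypeError("subject must be a TargetTranscript or CircularDNAzymeProbe")


def _arm_to_target_sense(arm: str) -> str:
    """RNA window (5'->3') that a DNA arm hybridizes."""
    return str(Seq(arm).reverse_complement().transcribe())


def _rebuild_probe(
    probe: CircularDNAzymeProbe, arm_5p: str, arm_3p: str, core: str, kind: str
) -> CircularDNAzymeProbe:
    sp = probe.spacer
    circle = (
        arm_5p + core + arm_3p + sp + probe.reference_region + sp + probe.barcode_anchor + sp
    )
    # the recognition window implied by the (possibly mutated) arms
    recognition = _arm_to_target_sense(arm_3p) + _arm_to_target_sense(arm_5p)
    return replace(
        probe,
        arm_5p=arm_5p,
        arm_3p=arm_3p,
        catalytic_core=core,
        circle_sequence=circle,
        kind=kind,
        recognition_rna=recognition,
    )


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _best_window_alignment(window: str, seq: str):
    """Best ungapped placement of ``window`` in ``seq``.

    Returns (offset, n_matches, mismatch positions within the window); if the
    sequence is shorter than the window, returns (None, 0, all positions).
    """
    w = len(window)
    if len(seq) < w:
        return None, 0, list(range(w))
    win = np.frombuffer(window.encode(), dtype=np.uint8)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    best_off, best_matches, best_mm = 0, -1, list(range(w))
    for off in range(len(seq) - w + 1):
        eq = s[off : off + w] == win
        m = int(eq.sum())
        if m > best_matches:
            best_off, best_matches = off, m
            best_mm = list(np.nonzero(~eq)[0])
    return best_off, best_matches, best_mm


def screen_specificity(
    probe: CircularDNAzymeProbe,
    background_seqs: list[TargetTranscript],
    critical_window: int = 8,
) -> pd.DataFrame:
    """Screen a probe against background transcripts.

    For each background sequence reports the longest contiguous
    complementarity of each arm, the total matched nucleotides at the best
    placement of the full recognition window, and whether cleavage is
    predicted to remain competent: any mismatch within ``critical_window`` nt
    of the junction on either side abolishes cleavage.
    """
    if probe.recognition_rna is None:
        raise ValueError("probe carries no recognition window to screen")
    L = probe.arm_len
    window = probe.recognition_rna
    arm5_sense = window[L:]  # target-sense RNA bound by arm_5p
    arm3_sense = window[:L]
    records = []
    for bg in background_seqs:
        seq = bg.sequence
        arm5_contig = _longest_common_substring(arm5_sense, seq)
        arm3_contig = _longest_common_substring(arm3_sense, seq)
        _, matches, mismatches = _best_window_alignment(window, seq)
        critical = [p for p in mismatches if L - critical_window <= p < L + critical_window]
        records.append(
            {
                "off_target_id": bg.id,
                "arm_5p_max_contig": min(arm5_contig, L),
                "arm_3p_max_contig": min(arm3_contig, L),
                "total_matched": matches,
                "cleavage_competent": len(critical) == 0 and matches > 0,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "off_target_id",
            "arm_5p_max_contig",
            "arm_3p_max_contig",
            "total_matched",
            "cleavage_competent",
        ],
    )


def emit_padlock_linker(probe: CircularDNAzymeProbe, linker_half: int = 10) -> tuple[str, str]:
    """Linearize the circle into a padlock oligo plus its splint linker.

    The linearization point is placed in the middle of the catalytic core so
    the ligation junction sits inside the core.  The linker reverse-
    complements the padlock 3' terminus followed by its 5' terminus
    (``linker_half`` nt each), templating the circularizing ligation;
    re-joining the padlock reproduces the circle exactly.
    """
    circle = probe.circle_sequence
    cut = (len(probe.arm_5p) + len(probe.catalytic_core) // 2) % len(circle)
    padlock = circle[cut:] + circle[:cut]
    linker = revcomp_dna(padlock[-linker_half:] + padlock[:linker_half])
    return padlock, linker


def read_targets_fasta(path) -> list[TargetTranscript]:
    """Read target RNAs from FASTA (T is auto-converted to U with a warning)."""
    return [TargetTranscript(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def probe_sheet(probes: list[CircularDNAzymeProbe]) -> pd.DataFrame:
    """One row per probe component, 5'->3' sequences, suitable for TSV export."""
    rows = []
    for p in probes:
        for part, seq in [
            ("arm_5p", p.arm_5p),
            ("catalytic_core", p.catalytic_core),
            ("arm_3p", p.arm_3p),
            ("reference_region", p.reference_region),
            ("barcode_anchor", p.barcode_anchor),
            ("circle", p.circle_sequence),
        ]:
            rows.append(
                {
                    "target_id": p.target_id,
                    "kind": p.kind,
                    "component": part,
                    "length_nt": len(seq),
                    "sequence_5p_to_3p": seq,
                }
            )
    return pd.DataFrame(rows)


def write_padlock_fasta(probes: list[CircularDNAzymeProbe], path) -> None:
    records = []
    for p in probes:
        padlock, linker = emit_padlock_linker(p)
        records.append(SeqRecord(Seq(padlock), id=f"{p.target_id}_{p.kind}_padlock", description=""))
        records.append(SeqRecord(Seq(linker), id=f"{p.target_id}_{p.kind}_linker", description=""))
    SeqIO.write(records, path, "fasta")
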