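"""Synthetic genomes with planted proviruses of known age and family structure.

The generator emulates the study conditions every pipeline stage is tested
against: a neutral i.i.d. background genome carrying full
5'LTR-gag-pro-pol-env-3'LTR proviruses whose two LTRs were identical at
insertion and have since diverged at a known per-site rate; multicopy
families of highly similar recent insertions; and a subset of copies whose
env gene is disrupted by in-frame stop codons (mutational decay). Ground
truth (insert coordinates, true age, family label, ORF intactness, planted
motif positions) is emitted alongside the FASTA so recovery can be checked
exactly.

Mutation model: per-site Bernoulli substitutions, at most one hit per site
(no multiple-hit correction; bias < 1% for the d <= 0.1 regime of interest).
Each LTR copy is mutated independently with per-site probability p =
expected_d / 2, so the expected pairwise LTR distance matches age x rate
under the chosen age convention. Indels are off by default; an optional
indel mode (geometric lengths, rate one tenth of the substitution rate)
exists to stress alignment. A few junction bases around the env gene
(its ATG, terminal stop, and the stop-codon pad immediately upstream) are
held fixed in intact copies so that ORF-intactness ground truth stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .families_consensus import pairwise_identity
from .env_features import find_furin_site, find_rdr_motif
from .orf_finder import find_orfs
from .profile_hmm import (
    AMINO_ALPHABET,
    PhmmProfile,
    calibrate_profile,
    profile_from_sequence,
)
from .sequence_io import (
    CODON_TABLE,
    GenomeSequence,
    Gff3Feature,
    GenomicInterval,
    STOP_CODONS,
    reverse_complement,
    translate,
)

# stop codons in every reading frame: TAG at offsets 0, 4, 8, ... (all mod 3)
STOP_PAD = "TAGA" * 6

_SENSE_CODONS = sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*")
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in _SENSE_CODONS:
    _CODONS_BY_AA.setdefault(CODON_TABLE[_c], []).append(_c)


@dataclass(frozen=True)
class ProvirusTruth:
    insert_interval: GenomicInterval
    family: str
    true_age: float
    ltr_intervals: tuple[GenomicInterval, GenomicInterval]  # genomic order
    env_interval: GenomicInterval
    env_intact: bool
    planted_furin: int  # aa position in the env template
    planted_rdr: int
    expected_d: float


@dataclass(frozen=True)
class SimConfig:
    seed: int = 20230417
    background_length: int = 2_000_000
    gc_content: float = 0.42
    n_families: int = 3
    copies_per_family: tuple[int, ...] = (8, 2, 2)
    ltr_len: int = 600
    age_grid: tuple[float, ...] = (0.5, 1.5, 5.0)
    rate: float = 2.6e-3
    age_convention: str = "one_lineage"
    decay_fraction: float = 1 / 3
    min_spacing: int = 25_000
    indel_mode: bool = False
    contig_name: str = "sim_chr1"

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if len(self.copies_per_family) != self.n_families:
            raise ValueError("copies_per_family must list one count per family")
        if self.age_convention not in ("one_lineage", "two_lineage"):
            raise ValueError("age_convention must be 'one_lineage' or 'two_lineage'")


@dataclass
class FamilyTemplates:
    name: str
    env_nt: str  # ATG..stop, no internal stops
    gag_nt: str
    pro_nt: str
    pol_nt: str
    ltr_nt: str
    furin_pos: int
    rdr_pos: int

    @property
    def env_aa(self) -> str:
        return translate(self.env_nt)[:-1]  # drop terminal '*'


def expected_distance(age: float, rate: float, convention: str) -> float:
    """Expected pairwise LTR p-distance at a given age under a convention."""
    return age * rate if convention == "one_lineage" else 2.0 * age * rate


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 20, size=length)
    return "".join(AMINO_ALPHABET[i] for i in idx)


def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_BY_AA[a][rng.integers(0, len(_CODONS_BY_AA[a]))] for a in aa
    )


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return "".join("ACGT"[i] for i in idx)


def make_env_template(
    rng: np.random.Generator, length: int = 450
) -> tuple[str, int, int]:
    """ATG-initiated env ORF with one RDR motif in SU and a furin site.

    Returns (nucleotide sequence including the terminal stop codon,
    planted furin cleavage position, planted RDR motif start), both amino
    acid coordinates. The furin site leaves well over 80 residues of TM
    tail; spurious extra furin/RDR matches are scrubbed.
    """
    if length < 420:
        raise ValueError("env template must be at least 420 codons")
    rdr_pos = int(rng.integers(80, 140))
    furin_motif_start = length - 180
    for _ in range(50):
        aa = list("M" + _random_protein(rng, length - 1))
        aa[rdr_pos : rdr_pos + 11] = (
            "SDGGG" + _random_protein(rng, 2) + "D" + _random_protein(rng, 2) + "R"
        )
        aa[furin_motif_start : furin_motif_start + 4] = (
            "R" + _random_protein(rng, 1) + ("R" if rng.integers(2) else "K") + "R"
        )
        seq = "".join(aa)
        cleavage = furin_motif_start + 4
        # scrub accidental furin motifs that would out-compete the planted
        # (C-terminal-most admissible) site, and accidental RDR motifs
        ok = True
        site = find_furin_site(seq)
        if site != cleavage:
            ok = False
        if find_rdr_motif(seq) != [rdr_pos]:
            ok = False
        if ok:
            nt = _reverse_translate(seq, rng)
            stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
            return nt + stop, cleavage, rdr_pos
    raise RuntimeError("failed to build a clean env template")


def make_family_templates(
    name: str, rng: np.random.Generator, config: SimConfig
) -> FamilyTemplates:
    env_nt, furin_pos, rdr_pos = make_env_template(rng)
    gag_nt = "ATG" + _reverse_translate(_random_protein(rng, 449), rng) + "TAA"
    pro_nt = "ATG" + _reverse_translate(_random_protein(rng, 249), rng) + "TAA"
    pol_nt = "ATG" + _reverse_translate(_random_protein(rng, 799), rng) + "TAA"
    ltr_nt = _random_nt(rng, config.ltr_len, config.gc_content)
    return FamilyTemplates(
        name=name,
        env_nt=env_nt,
        gag_nt=gag_nt,
        pro_nt=pro_nt,
        pol_nt=pol_nt,
        ltr_nt=ltr_nt,
        furin_pos=furin_pos,
        rdr_pos=rdr_pos,
    )


def _mutate(
    seq: str, p: float, rng: np.random.Generator, indel_mode: bool = False
) -> str:
    """Per-site Bernoulli substitutions; optional geometric indels at p/10."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    bases = b"ACGT"
    for i in hits:
        choices = [b for b in bases if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    out = arr.tobytes().decode()
    if indel_mode and p > 0:
        out_list = list(out)
        n_indels = rng.binomial(len(out_list), p / 10.0)
        for _ in range(n_indels):
            pos = int(rng.integers(0, len(out_list)))
            size = int(rng.geometric(0.5))
            if rng.integers(2):
                out_list[pos:pos] = _random_nt(rng, size, 0.5)
            else:
                del out_list[pos : pos + size]
        out = "".join(out_list)
    return out


def simulate_ltr_pair(
    ltr_len: int,
    age: float,
    rate: float,
    convention: str,
    rng: np.random.Generator,
    gc: float = 0.42,
    indel_mode: bool = False,
) -> tuple[str, str]:
    """An LTR pair diverged from a common template to the expected distance."""
    template = _random_nt(rng, ltr_len, gc)
    p = expected_distance(age, rate, convention) / 2.0
    return (
        _mutate(template, p, rng, indel_mode),
        _mutate(template, p, rng, indel_mode),
    )


def _plant_stops(
    env_seq: list[str], env_start: int, env_len_codons: int, rng: np.random.Generator
) -> None:
    """Disrupt env with 1-3 in-frame stops, the first placed so that no
    sub-ORF of 400+ codons survives on either side."""
    lo = max(10, env_len_codons - 395)
    hi = min(env_len_codons - 10, 395)
    first = int(rng.integers(lo, hi + 1))
    codons = [first] + [
        int(rng.integers(10, env_len_codons - 10))
        for _ in range(int(rng.integers(0, 3)))
    ]
    for c in codons:
        pos = env_start + 3 * c
        env_seq[pos : pos + 3] = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]


def make_provirus(
    templates: FamilyTemplates,
    age: float,
    config: SimConfig,
    rng: np.random.Generator,
    intact: bool = True,
) -> tuple[str, dict]:
    """Assemble and mutate one provirus copy.

    Returns the provirus sequence and a layout dict with provirus-local
    coordinates of the LTRs and the env ORF (terminal stop included).
    """
    spacer = lambda: _random_nt(rng, 20, config.gc_content) + STOP_PAD  # noqa: E731
    parts = [
        templates.ltr_nt,
        spacer(),
        templates.gag_nt,
        spacer(),
        templates.pro_nt,
        spacer(),
        templates.pol_nt,
        spacer(),
        templates.env_nt,
        spacer()[: len(STOP_PAD)],
        templates.ltr_nt,
    ]
    lens = [len(x) for x in parts]
    starts = np.concatenate([[0], np.cumsum(lens)])
    env_start = int(starts[8])
    env_end = int(starts[9])
    ltr5 = (0, lens[0])
    ltr3 = (int(starts[10]), int(starts[10] + lens[10]))
    template_seq = "".join(parts)

    d_exp = expected_distance(age, config.rate, config.age_convention)
    p = d_exp / 2.0
    # mutate the two LTRs independently (indels, when enabled, only stress
    # the LTR alignment), then the internal region with substitutions only
    # so internal coordinates stay exact
    mut5 = _mutate(parts[0], p, rng, config.indel_mode)
    internal_tpl = template_seq[lens[0] : ltr3[0]]
    internal = _mutate(internal_tpl, p, rng, False)
    mut3 = _mutate(parts[10], p, rng, config.indel_mode)
    shift = len(mut5) - lens[0]
    env_start += shift
    env_end += shift
    seq = list(mut5 + internal + mut3)

    if intact:
        # hold env junction bases fixed so intactness ground truth is exact
        seq[env_start : env_start + 3] = "ATG"
        tpl_off = env_start - shift  # template coordinate of env start
        seq[env_end - 3 : env_end] = template_seq[tpl_off + (env_end - env_start) - 3 : tpl_off + (env_end - env_start)]
        pad_start = env_start - len(STOP_PAD)
        seq[pad_start:env_start] = template_seq[tpl_off - len(STOP_PAD) : tpl_off]
        # revert any mutation that created an in-frame stop inside env
        for pos in range(env_start + 3, env_end - 3, 3):
            if "".join(seq[pos : pos + 3]) in STOP_CODONS:
                tpos = pos - shift
                seq[pos : pos + 3] = template_seq[tpos : tpos + 3]
    else:
        env_len_codons = (env_end - env_start) // 3 - 1
        _plant_stops(seq, env_start, env_len_codons, rng)

    layout = {
        "ltr5": (0, len(mut5)),
        "ltr3": (len(mut5) + len(internal), len(seq)),
        "env": (env_start, env_end),
        "expected_d": d_exp,
    }
    return "".join(seq), layout


def _decay_counts(copies: tuple[int, ...], fraction: float) -> list[int]:
    """Largest-remainder apportionment of the decayed-copy count."""
    total = round(sum(copies) * fraction)
    raw = [c * fraction for c in copies]
    counts = [math.floor(x) for x in raw]
    # remainder ties go to the family with fewest decayed copies so decay is
    # spread across families rather than concentrated in the largest one
    remainders = sorted(
        range(len(copies)), key=lambda i: (-(raw[i] - counts[i]), counts[i], i)
    )
    for i in remainders:
        if sum(counts) >= total:
            break
        if counts[i] < copies[i]:
            counts[i] += 1
    return counts


def make_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, list[ProvirusTruth], list[FamilyTemplates]]:
    """Background genome with planted proviruses and exact ground truth."""
    rng = np.random.default_rng(config.seed)
    families: list[FamilyTemplates] = []
    for i in range(config.n_families):
        for _ in range(50):
            cand = make_family_templates(f"F{i + 1}", rng, config)
            if all(
                pairwise_identity(cand.env_aa, f.env_aa) < 80.0 for f in families
            ):
                families.append(cand)
                break
        else:
            raise RuntimeError("could not generate divergent family templates")

    # build all provirus copies first so packing is exact
    proviruses: list[tuple[str, dict, str, float, bool]] = []
    for fam, n_copies, n_decay in zip(
        families,
        config.copies_per_family,
        _decay_counts(config.copies_per_family, config.decay_fraction),
    ):
        for c in range(n_copies):
            age = config.age_grid[c % len(config.age_grid)]
            intact = c < n_copies - n_decay
            seq, layout = make_provirus(fam, age, config, rng, intact=intact)
            proviruses.append((seq, layout, fam.name, age, intact))

    total_prov = sum(len(p[0]) for p in proviruses)
    n = len(proviruses)
    slack = config.background_length - total_prov - (n + 1) * config.min_spacing
    if slack < 0:
        raise ValueError(
            "infeasible packing: background too short for the requested "
            "insertions at the minimum spacing"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    background = _random_nt(
        rng, config.background_length - total_prov, config.gc_content
    )

    pieces: list[str] = []
    truths: list[ProvirusTruth] = []
    cursor_bg = 0  # consumed background
    genome_pos = 0
    contig = config.contig_name
    for idx, (seq, layout, fam_name, age, intact) in enumerate(proviruses):
        bg_before = int(offsets[idx]) + (idx + 1) * config.min_spacing - cursor_bg
        pieces.append(background[cursor_bg : cursor_bg + bg_before])
        cursor_bg += bg_before
        genome_pos += bg_before
        strand = "+" if rng.integers(2) else "-"
        plen = len(seq)
        inserted = seq if strand == "+" else reverse_complement(seq)
        pieces.append(inserted)

        def to_genome(local: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return genome_pos + local[0], genome_pos + local[1]
            return genome_pos + plen - local[1], genome_pos + plen - local[0]

        l5 = to_genome(layout["ltr5"])
        l3 = to_genome(layout["ltr3"])
        left, right = sorted([l5, l3])
        es, ee = to_genome(layout["env"])
        fam = next(f for f in families if f.name == fam_name)
        truths.append(
            ProvirusTruth(
                insert_interval=GenomicInterval(contig, genome_pos, genome_pos + plen, strand),
                family=fam_name,
                true_age=age,
                ltr_intervals=(
                    GenomicInterval(contig, left[0], left[1], strand),
                    GenomicInterval(contig, right[0], right[1], strand),
                ),
                env_interval=GenomicInterval(contig, es, ee, strand),
                env_intact=intact,
                planted_furin=fam.furin_pos,
                planted_rdr=fam.rdr_pos,
                expected_d=layout["expected_d"],
            )
        )
        genome_pos += plen
    pieces.append(background[cursor_bg:])
    genome = GenomeSequence(id=contig, seq="".join(pieces))

    # generation-time assertions: intact copies pass the 400-codon env
    # screen, decayed copies fail it (checked on the planted interval)
    for truth in truths:
        sub = truth.env_interval.extract(genome)
        orfs = find_orfs(sub, min_codons=400, both_strands=False)
        exact = [
            o
            for o in orfs
            if o.interval.start == 0 and o.interval.end == truth.env_interval.length
        ]
        if truth.env_intact and not exact:
            raise AssertionError("intact env copy fails the 400-codon screen")
        if not truth.env_intact and orfs:
            raise AssertionError("decayed env copy still passes the screen")
    return genome, truths, families


def truth_features(truths: list[ProvirusTruth]) -> list[Gff3Feature]:
    """Ground truth as GFF3 features (provirus, LTRs, env)."""
    feats: list[Gff3Feature] = []
    for i, t in enumerate(truths):
        attrs = (
            f"ID=provirus{i + 1};family={t.family};age_my={t.true_age:g};"
            f"env_intact={'true' if t.env_intact else 'false'}"
        )
        feats.append(Gff3Feature(interval=t.insert_interval, type="provirus", attributes=attrs))
        for which, iv in zip(("ltr_left", "ltr_right"), t.ltr_intervals):
            feats.append(
                Gff3Feature(
                    interval=iv,
                    type="long_terminal_repeat",
                    attributes=f"Parent=provirus{i + 1};side={which}",
                )
            )
        feats.append(
            Gff3Feature(
                interval=t.env_interval,
                type="env_orf",
                attributes=f"Parent=provirus{i + 1}",
            )
        )
    return feats


def build_profile_db(
    families: list[FamilyTemplates], seed: int
) -> tuple[list[PhmmProfile], dict[str, str]]:
    """Profiles for each family's env/gag/pro/pol, calibrated, plus class map."""
    profiles: list[PhmmProfile] = []
    class_map: dict[str, str] = {}
    for i, fam in enumerate(families):
        for gene, nt in (
            ("env", fam.env_nt),
            ("gag", fam.gag_nt),
            ("pro", fam.pro_nt),
            ("pol", fam.pol_nt),
        ):
            aa = translate(nt)[:-1]
            prof = profile_from_sequence(f"{fam.name}_{gene}", aa)
            calibrate_profile(
                prof, seed=(seed * 100 + i * 10 + len(profiles)) % (2**31 - 1),
                n_samples=100, seq_len=300,
            )
            profiles.append(prof)
            class_map[prof.name] = gene
    return profiles, class_map
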