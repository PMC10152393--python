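"""End-to-end pipeline: genome -> env ORFs -> proviruses -> families -> dating.

Stages, in order, with per-stage logging of the headline counts:

1. six-frame ORF screen (>= 400 codons, ATG to stop) on every contig;
2. profile-HMM classification of the ORF translations against an
   env/gag/pro/pol profile database at E <= 1e-10;
3. per env ORF: +/-10-kbp window, direct-repeat (LTR) calling, provirus
   delimitation and internal ORF structure labeling;
4. LTR-pair dating (p-distance -> age under the neutral rate);
5. family clustering of env ORFs, multiple alignment, column trimming and
   plurality consensus for multicopy families; NJ tree over families;
6. Env feature annotation (furin site, TM region, RDR motif).

All artifacts are plain text (FASTA/GFF3/TSV/Newick) and reruns with the
same inputs are byte-identical: nothing in the pipeline itself draws random
numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import divergence_dating as dating
from . import env_features
from . import families_consensus as fam
from . import ltr_detection as ltr
from . import orf_finder
from . import profile_hmm as phmm
from . import sequence_io as sio
from .config import PipelineParams

logger = logging.getLogger("erv_env_miner")


@dataclass
class PipelineReport:
    orfs: pd.DataFrame          # all screened ORFs with their best hit
    env_orfs: pd.DataFrame      # per env ORF: locus, family, hit, E
    proviruses: pd.DataFrame    # per env ORF: LTR coords, identity, d, age
    families: pd.DataFrame      # name, copy number, members
    env_annotations: pd.DataFrame
    counts: dict = field(default_factory=dict)
    calls: list = field(default_factory=list)
    family_objects: list = field(default_factory=list)
    consensus_nt: dict = field(default_factory=dict)
    consensus_aa: dict = field(default_factory=dict)
    newick: str | None = None


def _load_genome(genome) -> list[sio.GenomeSequence]:
    if isinstance(genome, (str, Path)):
        return sio.read_fasta(genome)
    return list(genome)


def _load_profiles(profiles) -> list[phmm.PhmmProfile]:
    if isinstance(profiles, (str, Path)):
        path = Path(profiles)
        if path.is_dir():
            out: list[phmm.PhmmProfile] = []
            for f in sorted(path.glob("*.hmm")):
                out.extend(phmm.parse_hmmer3(f))
            return out
        return phmm.parse_hmmer3(path)
    return list(profiles)


def run_pipeline(
    genome,
    profiles,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    class_map: dict[str, str] | str | Path | None = None,
) -> PipelineReport:
    """Run all stages and write artifacts under ``out_dir``."""
    params = params or PipelineParams()
    for maybe_path in (genome, profiles, class_map):
        if isinstance(maybe_path, (str, Path)) and not Path(maybe_path).exists():
            raise FileNotFoundError(f"input not found: {maybe_path}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = _load_genome(genome)
    profile_list = _load_profiles(profiles)
    if isinstance(class_map, (str, Path)):
        class_map = phmm.read_class_map(class_map)
    if class_map is None:
        # fall back to the suffix after the last '_' in the profile name
        class_map = {
            p.name: p.name.rsplit("_", 1)[-1].lower() for p in profile_list
        }

    # stage 1: ORF screen
    orfs: list[orf_finder.OrfRecord] = []
    for contig in contigs:
        orfs.extend(orf_finder.find_orfs(contig, params.min_codons))
    logger.info("orf_screen: %d ORFs >= %d codons", len(orfs), params.min_codons)

    # stage 2: profile-HMM classification
    hits = (
        phmm.classify_orfs(orfs, profile_list, class_map, params.e_threshold)
        if orfs
        else []
    )
    hits_by_id = {h.orf_id: h for h in hits}
    env_orfs = [o for o in orfs if hits_by_id.get(o.id, None) and hits_by_id[o.id].gene_class == "env"]
    logger.info(
        "hmm_scan: %d hits at E<=%g (%d env)",
        len(hits), params.e_threshold, len(env_orfs),
    )

    # stage 3: provirus delimitation
    genome_by_id = {c.id: c for c in contigs}
    calls: list[ltr.ProvirusCall] = []
    for orf in env_orfs:
        contig = genome_by_id[orf.interval.contig]
        window, offset = ltr.extract_window(contig, orf, params.flank)
        candidates = ltr.find_direct_repeats(
            window,
            min_ltr_len=params.min_ltr_len,
            max_ltr_len=params.max_ltr_len,
            min_identity=params.min_ltr_identity,
            k=params.seed_k,
            band=params.band,
            contig=orf.interval.contig,
            offset=offset,
        )
        call = ltr.call_provirus(orf, candidates)
        internal: list = []
        if call.ltr_pair is not None:
            prov_iv = call.provirus_interval
            prov_seq = sio.GenomicInterval(
                prov_iv.contig, prov_iv.start, prov_iv.end, orf.interval.strand
            ).extract(contig)
            internal_orfs = orf_finder.annotate_provirus_orfs(
                prov_seq, params.provirus_orf_min_nt
            )
            labels = phmm.classify_orfs(
                [o for o in internal_orfs if o.mode == orf_finder.START_TO_STOP],
                profile_list,
                class_map,
                params.e_threshold,
            )
            label_by_id = {h.orf_id: h.gene_class for h in labels}
            internal = [(o, label_by_id.get(o.id)) for o in internal_orfs]
            call = ltr.ProvirusCall(
                env_orf=orf, ltr_pair=call.ltr_pair, internal_orfs=internal
            )
        calls.append(call)
    n_pairs = sum(1 for c in calls if c.ltr_pair is not None)
    logger.info("ltr_calling: %d/%d env ORFs with an LTR pair", n_pairs, len(calls))

    # stage 4: dating
    ages: dict[str, dating.AgeEstimate | None] = {}
    for call in calls:
        if call.ltr_pair is None:
            ages[call.env_orf.id] = None
            continue
        contig = genome_by_id[call.env_orf.interval.contig]
        ltr5 = contig.seq[call.ltr_pair.left.start : call.ltr_pair.left.end]
        ltr3 = contig.seq[call.ltr_pair.right.start : call.ltr_pair.right.end]
        ages[call.env_orf.id] = dating.date_ltr_pair(
            ltr5, ltr3, params.rate, params.convention
        )

    # stage 5: families and consensus
    families: list[fam.EnvFamily] = []
    consensus_nt: dict[str, str] = {}
    consensus_aa: dict[str, str] = {}
    newick = None
    if env_orfs:
        aa_by_id = {o.id: o.aa_seq.rstrip("*") for o in env_orfs}
        nt_by_id = {o.id: o.nt_seq for o in env_orfs}
        families = fam.cluster_families(
            aa_by_id, params.family_identity_threshold
        )
        for family in families:
            if family.copy_number < 2:
                rep = family.members[0]
                family.consensus_nt = nt_by_id[rep]
                family.consensus_aa = aa_by_id[rep]
            else:
                msa_nt = fam.progressive_msa(
                    [(m, nt_by_id[m]) for m in family.members]
                )
                family.consensus_nt = fam.consensus(
                    fam.trim_sparse_columns(msa_nt, params.min_residue_fraction)
                )
                msa_aa = fam.progressive_msa(
                    [(m, aa_by_id[m]) for m in family.members]
                )
                family.consensus_aa = fam.consensus(
                    fam.trim_sparse_columns(msa_aa, params.min_residue_fraction)
                )
            consensus_nt[family.name] = family.consensus_nt
            consensus_aa[family.name] = family.consensus_aa
        if len(families) >= 2:
            import numpy as np

            names = [f.name for f in families]
            n = len(names)
            dm = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    ident = fam.pairwise_identity(
                        families[i].consensus_aa, families[j].consensus_aa
                    )
                    dm[i, j] = dm[j, i] = 1.0 - ident / 100.0
            newick = fam.nj_tree(dm, names)
    logger.info("families: %d (copy numbers %s)",
                len(families), [f.copy_number for f in families])

    # stage 6: Env annotation
    annotations = {
        o.id: env_features.annotate_env(o.aa_seq.rstrip("*"), params.min_tail)
        for o in env_orfs
    }

    report = _build_report(
        orfs, hits_by_id, env_orfs, calls, ages, families, annotations
    )
    report.calls = calls
    report.family_objects = families
    report.consensus_nt = consensus_nt
    report.consensus_aa = consensus_aa
    report.newick = newick
    report.counts = {
        "orfs_screened": len(orfs),
        "hits": len(hits),
        "env_orfs": len(env_orfs),
        "ltr_pairs": n_pairs,
        "families": len(families),
    }
    _write_artifacts(report, orfs, env_orfs, calls, out)
    return report


def _fmt_age(est: dating.AgeEstimate | None, col: str) -> str:
    if est is None:
        return "-"
    if col == "identity":
        return f"{est.identity_pct:.1f}"
    if col == "d":
        return f"{est.p_distance:.6f}"
    if col == "age":
        return f"{est.age_my:.3f}"
    raise KeyError(col)


def _build_report(orfs, hits_by_id, env_orfs, calls, ages, families, annotations):
    fam_by_member = {
        m: f.name for f in families for m in f.members
    }
    orf_rows = []
    for o in orfs:
        hit = hits_by_id.get(o.id)
        orf_rows.append(
            {
                "orf_id": o.id,
                "orf_length_aa": o.aa_len,
                "chromosome": o.interval.contig,
                "locus": f"{o.interval.start}-{o.interval.end}",
                "direction": o.interval.strand,
                "profile": hit.profile_name if hit else "-",
                "gene_class": hit.gene_class if hit else "-",
                "bit_score": f"{hit.bit_score:.2f}" if hit else "-",
                "evalue": f"{hit.evalue:.3e}" if hit else "-",
            }
        )
    env_rows = [
        dict(
            row,
            family=fam_by_member.get(row["orf_id"], "-"),
        )
        for row in orf_rows
        if row["gene_class"] == "env"
    ]
    prov_rows = []
    for call in calls:
        est = ages.get(call.env_orf.id)
        pair = call.ltr_pair
        prov_rows.append(
            {
                "orf_id": call.env_orf.id,
                "ltr5": f"{pair.left.start}-{pair.left.end}" if pair else "-",
                "ltr3": f"{pair.right.start}-{pair.right.end}" if pair else "-",
                "ltr_identity_pct": _fmt_age(est, "identity"),
                "p_distance": _fmt_age(est, "d"),
                "age_my": _fmt_age(est, "age"),
                "convention": est.convention if est else "-",
            }
        )
    fam_rows = [
        {
            "family": f.name,
            "copy_number": f.copy_number,
            "members": ",".join(f.members),
        }
        for f in families
    ]
    ann_rows = []
    for o in env_orfs:
        ann = annotations[o.id]
        ann_rows.append(
            {
                "orf_id": o.id,
                # motif positions are reported 1-based in tables
                "furin_pos": ann.furin_site + 1 if ann.furin_site is not None else "-",
                "tm_start": ann.furin_site + 1 if ann.furin_site is not None else "-",
                "tm_len": len(ann.tm_region) if ann.tm_region else "-",
                "rdr_positions": ",".join(str(p + 1) for p in ann.rdr_motif_positions)
                or "-",
            }
        )
    return PipelineReport(
        orfs=pd.DataFrame(orf_rows),
        env_orfs=pd.DataFrame(env_rows),
        proviruses=pd.DataFrame(prov_rows),
        families=pd.DataFrame(fam_rows),
        env_annotations=pd.DataFrame(ann_rows),
    )


def _write_artifacts(report, orfs, env_orfs, calls, out: Path) -> None:
    sio.write_fasta(
        [(o.id, o.aa_seq.rstrip("*")) for o in orfs], out / "orfs.faa"
    )
    with open(out / "orfs.bed", "w") as fh:
        for o in orfs:
            iv = o.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{o.id}\t{o.aa_len}\t{iv.strand}\n"
            )
    for name, df in (
        ("orfs.tsv", report.orfs),
        ("env_orfs.tsv", report.env_orfs),
        ("dating.tsv", report.proviruses),
        ("families.tsv", report.families),
        ("env_features.tsv", report.env_annotations),
    ):
        df.to_csv(out / name, sep="\t", index=False)
    feats: list[sio.Gff3Feature] = []
    for i, call in enumerate(calls):
        if call.ltr_pair is None:
            continue
        prov_iv = call.provirus_interval
        ident = f"{call.ltr_pair.identity_pct:.1f}"
        feats.append(
            sio.Gff3Feature(
                interval=prov_iv,
                type="provirus",
                attributes=f"ID=provirus{i + 1};env_orf={call.env_orf.id};"
                f"ltr_identity={ident}",
            )
        )
        for side, iv in (("left", call.ltr_pair.left), ("right", call.ltr_pair.right)):
            feats.append(
                sio.Gff3Feature(
                    interval=iv,
                    type="long_terminal_repeat",
                    attributes=f"Parent=provirus{i + 1};side={side}",
                )
            )
        for orf, label in call.internal_orfs:
            iv = sio.GenomicInterval(
                prov_iv.contig,
                prov_iv.start + orf.interval.start
                if prov_iv.strand == "+"
                else prov_iv.end - orf.interval.end,
                prov_iv.start + orf.interval.end
                if prov_iv.strand == "+"
                else prov_iv.end - orf.interval.start,
                prov_iv.strand,
            )
            feats.append(
                sio.Gff3Feature(
                    interval=iv,
                    type="open_reading_frame",
                    attributes=f"Parent=provirus{i + 1};mode={orf.mode};"
                    f"gene={label or 'unknown'}",
                )
            )
    sio.write_gff3(feats, out / "proviruses.gff3")
    if report.consensus_nt:
        sio.write_fasta(
            sorted(report.consensus_nt.items()), out / "consensus.fasta"
        )
        sio.write_fasta(
            sorted(report.consensus_aa.items()), out / "consensus_aa.faa"
        )
    tm_out = []
    for o in env_orfs:
        ann_row = report.env_annotations[report.env_annotations.orf_id == o.id]
        if not ann_row.empty and ann_row.iloc[0].tm_start != "-":
            start = int(ann_row.iloc[0].tm_start) - 1
            tm_out.append((o.id, o.aa_seq.rstrip("*")[start:]))
    if tm_out:
        sio.write_fasta(tm_out, out / "tm_regions.faa")
    if report.newick:
        (out / "families.nwk").write_text(report.newick + "\n")
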