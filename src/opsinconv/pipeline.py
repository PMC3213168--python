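"""End-to-end workflow: genotype report, diversity/divergence tables with
Z-tests, divergence-vs-polymorphism contingency tables, exon and intron
among-group trees, and the conversion-tract report.

Every stage is a plain function over the library types; ``run_full_analysis``
wires them together from a single config mapping and writes TSV / newick /
BED / JSON reports.  All randomness is funnelled through per-stage seeds
derived from one master seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from opsinconv import __version__
from opsinconv.alignment_io import (
    Alignment,
    RegionMap,
    complete_deletion_columns,
    read_fasta_alignment,
    write_fasta_alignment,
)
from opsinconv.diversity import (
    DistanceEstimate,
    bootstrap_se,
    nei_gojobori_pair,
    nucleotide_divergence,
    nucleotide_diversity,
    z_test_one_tailed,
)
from opsinconv.geneconv import detect_conversions
from opsinconv.genotype import genotype_record
from opsinconv.phylogeny import bootstrap_supports
from opsinconv.popgen import classify_alignment_sites, fisher_exact_two_sided
from opsinconv.simulate import SimulationConfig, group_ids, simulate_dataset, write_truth

logger = logging.getLogger(__name__)


def _stage_seed(master: int | None, stage: str) -> int | None:
    """Deterministic per-stage seed below 2^31 (stable across processes)."""
    if master is None:
        return None
    digest = hashlib.sha256(f"{int(master)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def single_copy_male_ids(aln: Alignment) -> list[str]:
    """IDs of male individuals carrying exactly one L and one M sequence."""
    per_ind: dict[tuple[str, str], dict[str, list[str]]] = {}
    for rec in aln:
        if rec.sex != "M" or rec.locus_tag not in ("L", "M"):
            continue
        d = per_ind.setdefault((rec.species_code, rec.individual), {"L": [], "M": []})
        d[rec.locus_tag].append(rec.raw_id)
    out = []
    for d in per_ind.values():
        if len(d["L"]) == 1 and len(d["M"]) == 1:
            out.extend(d["L"] + d["M"])
    return out


def genotype_report(aln: Alignment, region_map: RegionMap) -> pd.DataFrame:
    """Per-record tuning residues, gene call, hybrid flag and inferred lambda-max."""
    rows = []
    for rec in aln:
        if rec.locus_tag not in ("L", "M", "other"):
            continue
        g = genotype_record(rec, region_map)
        rows.append(
            {
                "id": rec.raw_id,
                "species": rec.species_code,
                "res180": g.res180,
                "res277": g.res277,
                "res285": g.res285,
                "gene_call": g.gene_call,
                "spectral_hybrid": g.spectral_hybrid,
                "lambda_max_nm": g.lambda_max_nm,
            }
        )
    return pd.DataFrame(rows)


def _codons_from_columns(
    bases: str, region_map: RegionMap, colset: set[int]
) -> list[str]:
    """Complete in-frame codons whose three sites all survived deletion."""
    out = []
    for s in region_map.codon_starts():
        if s in colset and s + 1 in colset and s + 2 in colset:
            out.append(bases[s : s + 3])
    return out


def _region_columns(region_map: RegionMap, columns: Sequence[int], names: set[str]) -> list[int]:
    return [
        j
        for j in columns
        if (reg := region_map.region_of_site(j)) is not None and reg.name in names
    ]


def _estimate_with_se(
    kind: str,
    seqs_a: list[str],
    seqs_b: list[str] | None,
    columns: list[int],
    site_class: str,
    reps: int,
    seed: int | None,
) -> DistanceEstimate:
    cols = np.asarray(columns)

    def stat(idx: np.ndarray) -> float:
        sub = cols[idx]
        if kind == "pi":
            return nucleotide_diversity(seqs_a, sub).value
        return nucleotide_divergence(seqs_a, seqs_b, sub).value

    base = (
        nucleotide_diversity(seqs_a, columns, site_class)
        if kind == "pi"
        else nucleotide_divergence(seqs_a, seqs_b, columns, site_class)
    )
    se = bootstrap_se(stat, len(columns), reps=reps, seed=seed)
    return DistanceEstimate(base.value, se, base.n_sites, site_class, kind)


def _ng_estimate_with_se(
    kind: str,
    codons_a: list[list[str]],
    codons_b: list[list[str]] | None,
    which: str,  # "syn" | "nonsyn"
    reps: int,
    seed: int | None,
) -> DistanceEstimate:
    """Nei-Gojobori per-site distance with codon-bootstrap SE."""
    import itertools

    n_codons = len(codons_a[0])

    def value_on(idx: np.ndarray | None) -> tuple[float, float]:
        def pick(cod):
            return cod if idx is None else [cod[i] for i in idx]

        if kind == "pi":
            pairs = list(itertools.combinations([pick(c) for c in codons_a], 2))
        else:
            pairs = [(pick(a), pick(b)) for a in codons_a for b in codons_b]
        vals, sites = [], []
        for a, b in pairs:
            c = nei_gojobori_pair(a, b)
            s = c.syn_sites if which == "syn" else c.nonsyn_sites
            d = c.syn_diffs if which == "syn" else c.nonsyn_diffs
            vals.append(d / s if s else 0.0)
            sites.append(s)
        return float(np.mean(vals)), float(np.mean(sites))

    value, n_sites = value_on(None)
    se = bootstrap_se(lambda idx: value_on(idx)[0], n_codons, reps=reps, seed=seed)
    cls = "synonymous" if which == "syn" else "nonsynonymous"
    return DistanceEstimate(value, se, n_sites, cls, kind)


def divergence_report(
    aln: Alignment,
    region_map: RegionMap,
    groups: Mapping[str, Sequence[str]],
    boot_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-species L-M divergence by region and site class, with Z-tests.

    Mirrors the bar-chart layout of the source analysis: exon 3/4/5, intron
    3/4, combined introns, synonymous and non-synonymous components, each
    with a bootstrap SE and a one-tailed Z P-value against the combined
    introns.
    """
    species = sorted({g.rsplit("_", 1)[0] for g in groups})
    rows = []
    for sp in species:
        if f"{sp}_L" not in groups or f"{sp}_M" not in groups:
            continue
        l_ids, m_ids = groups[f"{sp}_L"], groups[f"{sp}_M"]
        columns = complete_deletion_columns(aln, list(l_ids) + list(m_ids))
        colset = set(columns)
        L = [aln.get(i).bases for i in l_ids]
        M = [aln.get(i).bases for i in m_ids]
        intron_cols = _region_columns(region_map, columns, set(region_map.names("intron")))
        baseline = _estimate_with_se(
            "d", L, M, intron_cols, "intron", boot_reps, _stage_seed(seed, f"div/{sp}/int")
        )
        ests = {"introns": baseline}
        for name in region_map.names():
            cols = _region_columns(region_map, columns, {name})
            if cols:
                ests[name] = _estimate_with_se(
                    "d", L, M, cols, region_map.region(name).kind, boot_reps,
                    _stage_seed(seed, f"div/{sp}/{name}"),
                )
        cod_l = [_codons_from_columns(x, region_map, colset) for x in L]
        cod_m = [_codons_from_columns(x, region_map, colset) for x in M]
        if cod_l and cod_l[0]:
            for which in ("syn", "nonsyn"):
                ests[which] = _ng_estimate_with_se(
                    "d", cod_l, cod_m, which, boot_reps, _stage_seed(seed, f"div/{sp}/{which}")
                )
        for name, est in ests.items():
            p = z_test_one_tailed(est, baseline) if name != "introns" else None
            rows.append(
                {
                    "species": sp,
                    "region": name,
                    "site_class": est.site_class,
                    "d": est.value,
                    "se": est.se,
                    "n_sites": est.n_sites,
                    "z_p_vs_introns": p,
                }
            )
    return pd.DataFrame(rows)


def diversity_report(
    aln: Alignment,
    region_map: RegionMap,
    groups: Mapping[str, Sequence[str]],
    boot_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Within-group nucleotide diversity by exon/intron partition."""
    rows = []
    for gname in sorted(groups):
        ids = list(groups[gname])
        if len(ids) < 2:
            continue
        columns = complete_deletion_columns(aln, ids)
        seqs = [aln.get(i).bases for i in ids]
        for label, names in (
            ("exons", set(region_map.names("exon"))),
            ("introns", set(region_map.names("intron"))),
        ):
            cols = _region_columns(region_map, columns, names)
            if not cols:
                continue
            est = _estimate_with_se(
                "pi", seqs, None, cols, label.rstrip("s"), boot_reps,
                _stage_seed(seed, f"pi/{gname}/{label}"),
            )
            rows.append(
                {
                    "group": gname,
                    "partition": label,
                    "pi": est.value,
                    "se": est.se,
                    "n_sites": est.n_sites,
                }
            )
    return pd.DataFrame(rows)


def site_class_contrast_report(
    aln: Alignment, region_map: RegionMap, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-species 2x2 contrast of fixed L-M differences vs polymorphisms
    at synonymous sites vs introns, with two-sided Fisher P."""
    species = sorted({g.rsplit("_", 1)[0] for g in groups})
    rows = []
    for sp in species:
        if f"{sp}_L" not in groups or f"{sp}_M" not in groups:
            continue
        l_ids, m_ids = list(groups[f"{sp}_L"]), list(groups[f"{sp}_M"])
        if len(l_ids) < 2 or len(m_ids) < 2:
            continue
        columns = complete_deletion_columns(aln, l_ids + m_ids)
        cls = classify_alignment_sites(aln, l_ids, m_ids, region_map, columns)
        table = cls.table("synonymous", "intron")
        rows.append(
            {
                "species": sp,
                "div_syn": table[0, 0],
                "div_intron": table[0, 1],
                "poly_syn": table[1, 0],
                "poly_intron": table[1, 1],
                "fisher_p": fisher_exact_two_sided(table),
            }
        )
    return pd.DataFrame(rows)


def build_trees(
    aln: Alignment,
    region_map: RegionMap,
    groups: Mapping[str, Sequence[str]],
    boot_reps: int = 1000,
    seed: int | None = None,
    outgroup: str | None = None,
):
    """Among-group NJ trees for the exon and the intron partitions."""
    trees = {}
    all_ids = [i for ids in groups.values() for i in ids]
    columns = complete_deletion_columns(aln, all_ids)
    for label, kind in (("exon", "exon"), ("intron", "intron")):
        cols = _region_columns(region_map, columns, set(region_map.names(kind)))
        group_seqs = {g: [aln.get(i).bases for i in ids] for g, ids in groups.items()}
        trees[label] = bootstrap_supports(
            group_seqs, cols, reps=boot_reps, seed=_stage_seed(seed, f"tree/{label}"),
            outgroup=outgroup,
        )
    return trees["exon"], trees["intron"]


def conversion_report(
    aln: Alignment,
    region_map: RegionMap,
    ids: Sequence[str],
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    frags = detect_conversions(
        aln, region_map, ids=ids, alpha=alpha, n_perm=n_perm, seed=seed
    )
    rows = [
        {
            "seq1": f.seq1,
            "seq2": f.seq2,
            "start": f.start,
            "end": f.end,
            "n_poly_sites": f.n_poly_sites,
            "score": f.score,
            "global_sim_p": f.global_sim_p,
            "regions": ";".join(f"{n}:{frac:.2f}" for n, frac in f.regions_hit),
        }
        for f in frags
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq1", "seq2", "start", "end", "n_poly_sites", "score",
            "global_sim_p", "regions",
        ],
    )


def study_signatures(
    sim_cfg: SimulationConfig, n_perm: int = 600, alpha: float = 0.05
) -> dict:
    """Simulate one data set and evaluate the study's four contrasts on it.

    Returns the species-mean synonymous and intron L-M divergence, mean
    intron diversity per gene group, whether the exon and intron among-group
    NJ trees contain the all-L vs all-M duplication bipartition, the pooled
    fixed-difference/polymorphism table (synonymous vs intron), and the
    total and intronic length of significant conversion tracts.
    """
    from opsinconv.diversity import ng_divergence
    from opsinconv.phylogeny import among_group_distance_matrix, neighbor_joining

    aln, _ = simulate_dataset(sim_cfg)
    rm = sim_cfg.region_map()
    groups = group_ids(aln)
    species = sorted({g.rsplit("_", 1)[0] for g in groups})
    cols = complete_deletion_columns(aln)
    colset = set(cols)
    intron_cols = _region_columns(rm, cols, set(rm.names("intron")))
    exon_cols = _region_columns(rm, cols, set(rm.names("exon")))

    syn_d, intron_d, intron_pi = [], [], []
    pooled = np.zeros((2, 2), dtype=int)
    for sp in species:
        l_ids, m_ids = groups[f"{sp}_L"], groups[f"{sp}_M"]
        L = [aln.get(i).bases for i in l_ids]
        M = [aln.get(i).bases for i in m_ids]
        intron_d.append(nucleotide_divergence(L, M, intron_cols).value)
        cod_l = [_codons_from_columns(x, rm, colset) for x in L]
        cod_m = [_codons_from_columns(x, rm, colset) for x in M]
        syn_d.append(ng_divergence(cod_l, cod_m)[0].value)
        if len(L) >= 2:
            intron_pi.append(nucleotide_diversity(L, intron_cols).value)
        if len(M) >= 2:
            intron_pi.append(nucleotide_diversity(M, intron_cols).value)
        cls = classify_alignment_sites(aln, l_ids, m_ids, rm, cols)
        pooled += cls.table("synonymous", "intron")

    group_seqs = {g: [aln.get(i).bases for i in ids] for g, ids in groups.items()}
    l_side = frozenset(g for g in groups if g.endswith("_L"))
    full = frozenset(groups)
    key = min(l_side, full - l_side, key=sorted)

    def has_duplication_split(columns):
        labels, mat = among_group_distance_matrix(group_seqs, columns)
        return key in neighbor_joining(labels, mat).bipartitions()

    one_male = [f"1_{sp}_M_{locus}" for sp in species for locus in "LM"]
    frags = detect_conversions(
        aln, rm, ids=one_male, alpha=alpha, n_perm=n_perm,
        seed=_stage_seed(sim_cfg.seed, "geneconv"),
    )
    intron_names = set(rm.names("intron"))
    tract_total = sum(f.end - f.start + 1 for f in frags)
    tract_intron = sum(
        (f.end - f.start + 1) * sum(fr for n, fr in f.regions_hit if n in intron_names)
        for f in frags
    )
    return {
        "syn_divergence": float(np.mean(syn_d)),
        "intron_divergence": float(np.mean(intron_d)),
        "intron_diversity": float(np.mean(intron_pi)) if intron_pi else float("nan"),
        "exon_tree_has_duplication_split": has_duplication_split(exon_cols),
        "intron_tree_has_duplication_split": has_duplication_split(intron_cols),
        "site_class_table": pooled,
        "tract_total_length": float(tract_total),
        "tract_intron_length": float(tract_intron),
    }


def run_full_analysis(cfg: Mapping, outdir) -> dict:
    """Run the whole workflow from a config mapping; returns the manifest.

    The config provides either ``simulation`` (keyword arguments for
    :class:`SimulationConfig`) or ``alignment`` (FASTA path); optional keys:
    ``region_map`` (layout lengths), ``seed``, ``bootstrap_reps``,
    ``n_perm``, ``alpha``, ``males_only_single_copy`` (default true),
    ``outgroup``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    boot_reps = int(cfg.get("bootstrap_reps", 1000))
    n_perm = int(cfg.get("n_perm", 10000))
    alpha = float(cfg.get("alpha", 0.05))

    if ("simulation" in cfg) == ("alignment" in cfg):
        raise ValueError("config must specify exactly one of 'simulation' or 'alignment'")

    if "simulation" in cfg:
        sim_kwargs = dict(cfg["simulation"] or {})
        sim_kwargs.setdefault("seed", _stage_seed(seed, "simulate"))
        sim = SimulationConfig(**sim_kwargs)
        aln, truth = simulate_dataset(sim)
        region_map = sim.region_map()
        write_fasta_alignment(aln, outdir / "simulated_alignment.fasta")
        write_truth(truth, outdir / "simulation_truth.json")
    else:
        aln = read_fasta_alignment(cfg["alignment"])
        from opsinconv.alignment_io import default_opsin_region_map

        region_map = default_opsin_region_map(**(cfg.get("region_map") or {}))

    groups = {k: v for k, v in group_ids(aln).items() if len(v) > 0}
    lm_groups = {k: v for k, v in groups.items() if k.endswith(("_L", "_M"))}

    genotype_report(aln, region_map).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    divergence_report(
        aln, region_map, lm_groups, boot_reps, seed
    ).to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    diversity_report(
        aln, region_map, lm_groups, boot_reps, seed
    ).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    site_class_contrast_report(aln, region_map, lm_groups).to_csv(
        outdir / "site_class_contrast.tsv", sep="\t", index=False
    )

    exon_tree, intron_tree = build_trees(
        aln, region_map, lm_groups, boot_reps, seed, outgroup=cfg.get("outgroup")
    )
    (outdir / "exon_tree.nwk").write_text(exon_tree.newick(with_support=True) + "\n")
    (outdir / "intron_tree.nwk").write_text(intron_tree.newick(with_support=True) + "\n")

    males = (
        single_copy_male_ids(aln)
        if cfg.get("males_only_single_copy", True)
        else aln.ids()
    )
    conv = conversion_report(
        aln, region_map, males, alpha, n_perm, _stage_seed(seed, "geneconv")
    )
    conv.to_csv(outdir / "conversion_fragments.tsv", sep="\t", index=False)
    with open(outdir / "conversion_fragments.bed", "w") as fh:
        for _, row in conv.iterrows():
            fh.write(
                f"region\t{row.start - 1}\t{row.end}\t{row.seq1}|{row.seq2}\t"
                f"{row.global_sim_p:.4g}\n"
            )

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "bootstrap_reps": boot_reps,
        "n_perm": n_perm,
        "alpha": alpha,
        "n_records": len(aln),
        "alignment_length": aln.length,
        "groups": {k: len(v) for k, v in groups.items()},
        "haplotype_ids_used": males,
        "outputs": sorted({p.name for p in outdir.iterdir()} | {"manifest.json"}),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
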