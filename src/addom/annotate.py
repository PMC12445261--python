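"""Candidate-gene annotation by a symmetric proximity rule.

A variant is annotated to a gene when its position falls inside the gene span
or within a fixed flank (default 1 kb) on either side, strand-agnostically.
Coordinates are 1-based closed intervals throughout (GFF3 convention; BED
input is converted on read).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_gff3_genes",
    "read_bed_genes",
    "annotate",
    "summarize_candidates",
]


class ChromosomeMismatchError(ValueError):
    pass


def read_gff3_genes(path, feature_types=("gene",)) -> pd.DataFrame:
    """Gene spans from a GFF3 file (rows whose type is in ``feature_types``)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or "."
            rows.append(
                dict(
                    gene=gene, chrom=parts[0], start=int(parts[3]),
                    end=int(parts[4]), strand=parts[6],
                )
            )
    return _validate_genes(pd.DataFrame(rows))


def read_bed_genes(path) -> pd.DataFrame:
    """Gene spans from a >=4-column BED file (0-based half-open -> 1-based)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = pd.DataFrame(
        {
            "gene": df[3].astype(str),
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
            "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
        }
    )
    return _validate_genes(genes)


def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    if len(genes) and ((genes["start"] > genes["end"]).any() or (genes["start"] < 1).any()):
        raise ValueError("gene table has invalid coordinates (start>end or <1)")
    return genes.reset_index(drop=True)


def annotate(
    variants: pd.DataFrame, genes: pd.DataFrame, flank: int = 1000
) -> pd.DataFrame:
    """Map variants to genes within [start - flank, end + flank].

    ``variants`` needs columns ``chrom``/``pos`` (``id`` optional); ``genes``
    needs ``gene``/``chrom``/``start``/``end``.  Every qualifying gene is
    reported with its relation (genic / within-flank up- or downstream, in
    reference orientation) and distance to the gene span.
    """
    vchroms = set(map(str, variants["chrom"])) if len(variants) else set()
    gchroms = set(map(str, genes["chrom"])) if len(genes) else set()
    if vchroms and gchroms and not (vchroms & gchroms):
        raise ChromosomeMismatchError(
            "no chromosome names in common between variants and genes; "
            f"variants use {sorted(vchroms)[:5]}, genes use {sorted(gchroms)[:5]}"
        )

    out = []
    for chrom, vsub in variants.groupby(variants["chrom"].astype(str)):
        gsub = genes[genes["chrom"].astype(str) == chrom]
        if gsub.empty:
            continue
        gsub = gsub.sort_values("start").reset_index(drop=True)
        starts = gsub["start"].to_numpy(int)
        ends = gsub["end"].to_numpy(int)
        # prefix running maximum of (end + flank) bounds the backward scan
        run_max_end = np.maximum.accumulate(ends + flank)
        for _, v in vsub.iterrows():
            pos = int(v["pos"])
            hi = int(np.searchsorted(starts - flank, pos, side="right"))
            g = hi - 1
            while g >= 0 and run_max_end[g] >= pos:
                if starts[g] - flank <= pos <= ends[g] + flank:
                    if starts[g] <= pos <= ends[g]:
                        relation, dist = "genic", 0
                    elif pos < starts[g]:
                        relation, dist = "within-flank-upstream", starts[g] - pos
                    else:
                        relation, dist = "within-flank-downstream", pos - ends[g]
                    out.append(
                        dict(
                            variant=v.get("id", f"{chrom}:{pos}"), chrom=chrom,
                            pos=pos, gene=gsub["gene"].iloc[g],
                            relation=relation, distance=dist,
                        )
                    )
                g -= 1
    return pd.DataFrame(
        out, columns=["variant", "chrom", "pos", "gene", "relation", "distance"]
    )


def summarize_candidates(
    annot: pd.DataFrame, assoc: pd.DataFrame
) -> pd.DataFrame:
    """Per component: counts of suggestive/Bonferroni variants, distinct
    candidate genes, and per-chromosome variant tallies.

    ``assoc`` must carry TIER_A / TIER_D columns (see gwas.assign_tiers).
    """
    rows = []
    annotated_variants = set(annot["variant"]) if len(annot) else set()
    for comp, tier_col in (("additive", "TIER_A"), ("dominance", "TIER_D")):
        sig = assoc[assoc[tier_col].isin(["suggestive", "bonferroni"])]
        sig_ids = set(sig["ID"]) if len(sig) else set()
        genes = (
            sorted(set(annot.loc[annot["variant"].isin(sig_ids), "gene"]))
            if len(annot)
            else []
        )
        per_chrom = sig.groupby("CHR").size().to_dict() if len(sig) else {}
        rows.append(
            dict(
                component=comp,
                n_suggestive=int((sig[tier_col] == "suggestive").sum()),
                n_bonferroni=int((sig[tier_col] == "bonferroni").sum()),
                n_significant=len(sig),
                n_candidate_genes=len(genes),
                candidate_genes=",".join(genes),
                per_chromosome=";".join(
                    f"{c}:{k}" for c, k in sorted(per_chrom.items())
                ),
            )
        )
    return pd.DataFrame(rows)
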