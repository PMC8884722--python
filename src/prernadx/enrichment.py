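"""Over-representation analysis of selected RNA features.

Selected miRNAs/isomiRs are mapped to predicted target genes through a
user-supplied three-column target table (miRNA id, gene id, prediction
score) with a strict score cutoff (> 60 by default, the conventional
confidence bound for such predictions); mRNA features pass through as
themselves.  The mapped gene set is tested against user-supplied pathway
gene sets (GMT format) with a one-sided hypergeometric test and
Benjamini-Hochberg adjustment.  No pathway or target database content is
bundled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import RnaAnnotation


class EnrichmentError(ValueError):
    pass


@dataclass
class OraRow:
    pathway_id: str
    overlap: int
    pathway_size: int
    p_value: float
    q_value: float
    genes: tuple[str, ...]


def read_target_map(path: str | Path) -> pd.DataFrame:
    """Load a 3-column TSV of (mirna_id, gene_id, score)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["mirna_id", "gene_id", "score"],
        dtype={"mirna_id": str, "gene_id": str},
    )
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if df["score"].isna().any() or not df["score"].map(lambda v: v == v).all():
        raise EnrichmentError(f"{path}: non-finite scores")
    if (df["mirna_id"] == "").any() or (df["gene_id"] == "").any():
        raise EnrichmentError(f"{path}: empty identifiers")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse GMT pathway sets: name <tab> description <tab> gene..."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"{path}: malformed GMT line {line[:60]!r}")
        genes = {g for g in parts[2:] if g}
        if not genes:
            raise EnrichmentError(f"{path}: pathway {parts[0]!r} is empty")
        pathways[parts[0]] = genes
    if not pathways:
        raise EnrichmentError(f"{path}: no pathways found")
    return pathways


def map_targets(
    features: Sequence[str],
    annotation: Sequence[RnaAnnotation],
    target_map: pd.DataFrame,
    score_cutoff: float = 60.0,
) -> set[str]:
    """Map selected features to a target gene set.

    miRNA/isomiR features contribute targets with prediction score
    strictly above the cutoff; mRNA features pass through as themselves;
    other RNA classes are dropped (with a log note).
    """
    class_of = {a.feature_id: a.rna_class for a in annotation}
    genes: set[str] = set()
    dropped: list[str] = []
    strong = target_map[target_map["score"] > score_cutoff]
    by_mirna = strong.groupby("mirna_id")["gene_id"].agg(set).to_dict()
    for f in features:
        cls = class_of.get(f)
        if cls in ("miRNA", "isomiR"):
            genes |= by_mirna.get(f, set())
        elif cls == "mRNA":
            genes.add(f)
        else:
            dropped.append(f)
    if dropped:
        warnings.warn(
            f"{len(dropped)} feature(s) of unmapped RNA classes dropped "
            f"from target mapping (e.g. {dropped[0]!r})",
            UserWarning,
            stacklevel=2,
        )
    if not genes:
        warnings.warn("no mappable features; empty gene set", UserWarning,
                      stacklevel=2)
    return genes


def ora_test(
    selected: set[str],
    pathways: Mapping[str, set[str]],
    universe: set[str],
) -> list[OraRow]:
    """One-sided hypergeometric over-representation test per pathway.

    With N = |universe|, K = |pathway within the universe|, n =
    |selected|, the p-value is P(X >= overlap) for X hypergeometric;
    q-values are Benjamini-Hochberg across pathways.
    """
    stray = sorted(selected - universe)
    if stray:
        raise EnrichmentError(
            f"selected genes outside the universe: {stray[:10]}"
        )
    N = len(universe)
    n = len(selected)
    rows = []
    for pid in sorted(pathways):
        in_universe = pathways[pid] & universe
        if not in_universe:
            raise EnrichmentError(
                f"pathway {pid!r} has no genes in the universe"
            )
        K = len(in_universe)
        hits = tuple(sorted(selected & in_universe))
        k = len(hits)
        # P(X >= k); sf(k-1) so k = 0 gives exactly 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((pid, k, K, min(p, 1.0), hits))
    if not rows:
        return []
    _, q_values, _, _ = multipletests(
        [r[3] for r in rows], method="fdr_bh"
    )
    return [
        OraRow(
            pathway_id=pid, overlap=k, pathway_size=K,
            p_value=p, q_value=float(q), genes=hits,
        )
        for (pid, k, K, p, hits), q in zip(rows, q_values)
    ]


def default_universe(
    target_map: pd.DataFrame, annotation: Sequence[RnaAnnotation]
) -> set[str]:
    """All genes in the target map plus all mRNA feature ids."""
    genes = set(target_map["gene_id"])
    genes |= {a.feature_id for a in annotation if a.rna_class == "mRNA"}
    return genes
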