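"""Multi-locus sequence (MLS) concatenation of housekeeping proteins.

A finer-grained organismal-phylogeny proxy than 16S rRNA: the amino-acid
alignments of five housekeeping genes (rpoB, recA, atpD, dnaA, ftsZ by
default) are concatenated per strain, and a JTT distance matrix of the
concatenation serves as the species-distance reference.  Strains missing
any required gene are dropped (with a logged census), mirroring how a
complete-genes subset is carved out of a larger genome set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .distances import DistanceModel, jtt_ml_distance
from .errors import AlignmentError
from .io_formats import PROTEIN, Alignment, DistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_GENES = ("rpoB", "recA", "atpD", "dnaA", "ftsZ")

#: fewest strains for which a concatenation is useful downstream
MIN_STRAINS = 4


@dataclass(frozen=True)
class GeneSet:
    """Per-gene protein alignments keyed by gene name."""

    alignments: dict
    required_genes: tuple = DEFAULT_GENES

    def __post_init__(self):
        if not self.required_genes:
            raise ValueError("required_genes must be non-empty")
        missing = [g for g in self.required_genes if g not in self.alignments]
        if missing:
            raise KeyError(f"no alignment provided for genes {missing}")


def concatenate(gs: GeneSet) -> Alignment:
    """Join per-gene rows for strains present in every required gene.

    The retained-strain set is the intersection across genes (independent
    of gene order); row order follows the first required gene's alignment.
    """
    per_gene = [gs.alignments[g] for g in gs.required_genes]
    strain_sets = [set(a.labels) for a in per_gene]
    retained = set.intersection(*strain_sets)
    all_strains = set.union(*strain_sets)
    dropped = sorted(all_strains - retained)
    if dropped:
        logger.info(
            "MLS concatenation dropped %d/%d strains lacking >=1 gene: %s",
            len(dropped),
            len(all_strains),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if len(retained) < MIN_STRAINS:
        raise AlignmentError(
            f"only {len(retained)} strains have all required genes (need {MIN_STRAINS})"
        )
    order = [lab for lab in per_gene[0].labels if lab in retained]
    rows = ["".join(a.row(lab) for a in per_gene) for lab in order]
    return Alignment(tuple(order), tuple(rows), PROTEIN)


def mls_distance(gs: GeneSet, model: DistanceModel | None = None) -> DistanceMatrix:
    """JTT maximum-likelihood distances of the concatenated alignment."""
    return jtt_ml_distance(concatenate(gs), model or DistanceModel("JTT"))
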