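"""miRNA response element (MRE) prediction handling.

Parses miRanda and TargetScan outputs, keeps only (circRNA, miRNA) pairs
reported by **both** algorithms, and applies the post-hoc filters (drop 6mer
sites; drop hybrids with minimum free energy >= -20.0 kcal/mol, the boundary
removed inclusively).

A seed-site scanner is included so synthetic fixtures can be validated
without running either external predictor. Site types follow the canonical
definitions: a 6mer core is a Watson-Crick match of the target to miRNA
nucleotides 2-7; adding a match to nucleotide 8 on the 5' flank gives
7mer-m8; an adenine on the 3' flank (opposite miRNA nucleotide 1) gives
7mer-A1; both together give 8mer. Each position is reported once with its
strongest label (8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, NamedTuple, Sequence, Tuple

from Bio.Seq import Seq

from .records import MREPrediction, SITE_TYPES


class ParseError(ValueError):
    pass


class MirandaHit(NamedTuple):
    circ_id: str
    mirna_id: str
    score: float
    mfe: float
    position: int


class TargetScanHit(NamedTuple):
    circ_id: str
    mirna_id: str
    site_type: str
    position: int


# TargetScan emits historical spellings alongside the canonical vocabulary.
SITE_TYPE_ALIASES: Dict[str, str] = {
    "6mer": "6mer",
    "7mer-1a": "7mer-A1",
    "7mer-a1": "7mer-A1",
    "7mer-m8": "7mer-m8",
    "8mer": "8mer",
    "8mer-1a": "8mer",
}

#: specificity rank; higher is stronger
_SITE_RANK = {site: rank for rank, site in enumerate(SITE_TYPES)}


def parse_miranda(path: str) -> List[MirandaHit]:
    """Read per-hit lines of a miRanda run.

    Hit lines start with a single '>' and carry (miRNA, target, total score,
    total energy, miRNA span, target span, ...); '>>' summary lines and the
    surrounding log text are skipped.
    """
    hits: List[MirandaHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line.startswith(">") or line.startswith(">>"):
                continue
            fields = line.lstrip(">").split("\t")
            if len(fields) < 7:
                raise ParseError(
                    f"{path}:{lineno}: miRanda hit line with {len(fields)} fields"
                )
            try:
                score = float(fields[2])
                mfe = float(fields[3])
                position = int(fields[5])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score/energy/position"
                ) from None
            hits.append(MirandaHit(fields[1], fields[0], score, mfe, position))
    return hits


def parse_targetscan(path: str) -> List[TargetScanHit]:
    """Read TargetScan tabular output, normalising site-type spellings."""
    hits: List[TargetScanHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("a_Gene_ID", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{lineno}: TargetScan row with {len(fields)} fields"
                )
            raw_site = fields[8].strip()
            site = SITE_TYPE_ALIASES.get(raw_site.lower())
            if site is None:
                raise ParseError(
                    f"{path}:{lineno}: unknown site type {raw_site!r}"
                )
            try:
                position = int(fields[5]) - 1  # UTR_start is 1-based
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric site start") from None
            hits.append(TargetScanHit(fields[0], fields[1], site, position))
    return hits


def write_miranda(hits: Sequence[MirandaHit], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("# miRanda-style scan results\n")
        for h in hits:
            mirna_span = "2 8"
            target_end = h.position + 7
            handle.write(
                f">{h.mirna_id}\t{h.circ_id}\t{h.score:.2f}\t{h.mfe:.2f}\t"
                f"{mirna_span}\t{h.position}\t{target_end}\t7\t80.00\t85.00\n"
            )
        handle.write(">>summary omitted\n")


def write_targetscan(hits: Sequence[TargetScanHit], path: str) -> None:
    with open(path, "w") as handle:
        handle.write(
            "a_Gene_ID\tmiRNA_family_ID\tspecies_ID\tMSA_start\tMSA_end\t"
            "UTR_start\tUTR_end\tGroup_num\tSite_type\n"
        )
        for h in hits:
            handle.write(
                f"{h.circ_id}\t{h.mirna_id}\t9606\t{h.position + 1}\t"
                f"{h.position + 7}\t{h.position + 1}\t{h.position + 7}\t1\t"
                f"{h.site_type}\n"
            )


def intersect_predictions(
    miranda: Iterable[MirandaHit],
    targetscan: Iterable[TargetScanHit],
) -> List[MREPrediction]:
    """One MREPrediction per (circRNA, miRNA) pair present in BOTH inputs.

    Score and energy come from miRanda (best-scoring hit if several); site
    type and position come from TargetScan (strongest site if several). Pairs
    seen by only one algorithm are dropped.
    """
    best_miranda: Dict[Tuple[str, str], MirandaHit] = {}
    for hit in miranda:
        key = (hit.circ_id, hit.mirna_id)
        prev = best_miranda.get(key)
        if prev is None or hit.score > prev.score:
            best_miranda[key] = hit
    best_ts: Dict[Tuple[str, str], TargetScanHit] = {}
    for hit in targetscan:
        key = (hit.circ_id, hit.mirna_id)
        prev = best_ts.get(key)
        if prev is None or _SITE_RANK[hit.site_type] > _SITE_RANK[prev.site_type]:
            best_ts[key] = hit

    out: List[MREPrediction] = []
    for key in sorted(best_miranda.keys() & best_ts.keys()):
        mh, th = best_miranda[key], best_ts[key]
        out.append(
            MREPrediction(
                circ_id=key[0],
                mirna_id=key[1],
                miranda_score=mh.score,
                mfe=mh.mfe,
                site_type=th.site_type,
                position=th.position,
            )
        )
    return out


def filter_predictions(
    predictions: Iterable[MREPrediction],
    mfe_max: float = -20.0,
    drop_6mer: bool = True,
) -> List[MREPrediction]:
    """Post-hoc strict filter: keep mfe strictly below ``mfe_max`` (a hybrid
    at exactly the boundary is removed) and optionally drop 6mer sites."""
    kept = []
    for pred in predictions:
        if pred.mfe >= mfe_max:
            continue
        if drop_6mer and pred.site_type == "6mer":
            continue
        kept.append(pred)
    return kept


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _normalise(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    if any(base not in _COMPLEMENT for base in seq):
        raise ValueError(f"invalid characters in {what} sequence")
    return seq


def scan_seed_sites(
    target_seq: str, mirna_seq: str
) -> List[Tuple[int, str]]:
    """Find canonical seed sites of a miRNA on a target, 5'->3'.

    Returns ``(position, site_type)`` per site, where position is the 0-based
    start of the 6mer core match on the target. RNA (U) and DNA (T) alphabets
    are accepted interchangeably.
    """
    target = _normalise(target_seq, "target")
    mirna = _normalise(mirna_seq, "miRNA")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    # target core pairs antiparallel with miRNA nt 2-7
    core = str(Seq(mirna[1:7]).reverse_complement())
    m8_complement = _COMPLEMENT[mirna[7]]
    sites: List[Tuple[int, str]] = []
    for pos in range(len(target) - 5):
        if target[pos:pos + 6] != core:
            continue
        m8 = pos >= 1 and target[pos - 1] == m8_complement
        a1 = pos + 6 < len(target) and target[pos + 6] == "A"
        if m8 and a1:
            site = "8mer"
        elif m8:
            site = "7mer-m8"
        elif a1:
            site = "7mer-A1"
        else:
            site = "6mer"
        sites.append((pos, site))
    return sites


def scan_circular(
    mature_seq: str, mirna_seq: str
) -> List[Tuple[int, str, bool]]:
    """Scan a pseudo-circularised mature sequence for seed sites.

    The mature sequence is extended with its first ``len(miRNA) - 1``
    nucleotides so sites spanning the back-splice junction are visible. Only
    sites starting within the original sequence are reported (a start in the
    appended copy would duplicate a site already seen at its circular
    position); a site whose core crosses the junction is flagged.
    """
    mature = _normalise(mature_seq, "target")
    overhang = len(_normalise(mirna_seq, "miRNA")) - 1
    pseudo = mature + mature[:overhang]
    out = []
    for pos, site in scan_seed_sites(pseudo, mirna_seq):
        if pos >= len(mature):
            continue
        out.append((pos, site, pos + 6 > len(mature)))
    return out


def write_predictions(predictions: Sequence[MREPrediction], path: str) -> None:
    """Per-sample tab-separated MRE table (node/edge membership)."""
    with open(path, "w") as handle:
        handle.write(
            "circ_id\tmirna_id\tmiranda_score\tmfe\tsite_type\tposition\t"
            "junction_spanning\n"
        )
        for p in predictions:
            handle.write(
                f"{p.circ_id}\t{p.mirna_id}\t{p.miranda_score:.2f}\t"
                f"{p.mfe:.2f}\t{p.site_type}\t{p.position}\t"
                f"{str(p.junction_spanning).lower()}\n"
            )
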