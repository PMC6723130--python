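"""Brute-force string-level re-implementation of the consensus stage.

Deliberately naive (dict/string based, exhaustive pairwise distances) so
the vectorised pipeline can be checked against it on small fixtures.
"""

from collections import Counter

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
ANCHOR_LEN = 5


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def merge(r1: str, r2: str) -> str:
    oriented = revcomp(r2)
    return "".join(
        a if (a == b and a != "N") else "N" for a, b in zip(r1, oriented)
    )


def split_barcode(merged: str, umi_len: int) -> tuple[str, str]:
    barcode = (
        merged[:umi_len]
        + merged[len(merged) - umi_len :]
        + merged[umi_len : umi_len + ANCHOR_LEN]
    )
    insert = merged[umi_len : len(merged) - umi_len]
    return barcode, insert


def hamming(a: str, b: str) -> int:
    """N is an ordinary fifth symbol: it mismatches every base but
    matches another N (same semantics as the pipeline)."""
    return sum(x != y for x, y in zip(a, b))


def greedy_cluster(barcodes: list[str], max_mismatch: int) -> dict[str, int]:
    """Barcode -> bin id, visiting unique barcodes by support then name."""
    counts = Counter(barcodes)
    order = sorted(counts, key=lambda bc: (-counts[bc], bc))
    assignment: dict[str, int] = {}
    founders: list[str] = []
    for barcode in order:
        hit = None
        for bin_id, founder in enumerate(founders):
            if (
                sum(x != y for x, y in zip(barcode, founder)) <= max_mismatch
            ):
                hit = bin_id
                break
        if hit is None:
            hit = len(founders)
            founders.append(barcode)
        assignment[barcode] = hit
    return assignment


def collapse(members: list[str], min_reads: int, agreement: float):
    if len(members) < min_reads:
        return None
    out = []
    for column in zip(*members):
        tally = Counter(b for b in column if b != "N")
        if not tally:
            out.append("N")
            continue
        top = max(tally.values())
        winners = [b for b, c in tally.items() if c == top]
        if len(winners) > 1 or top < agreement * len(members) - 1e-9:
            out.append("N")
        else:
            out.append(winners[0])
    return "".join(out)


def run(pairs: list[tuple[str, str]], umi_len: int = 12, min_reads: int = 5,
        agreement: float = 0.75, max_mismatch: int = 1):
    """Full brute-force pipeline; returns a multiset of (seq, support)."""
    barcodes, inserts = [], []
    for r1, r2 in pairs:
        merged = merge(r1, r2)
        barcode, insert = split_barcode(merged, umi_len)
        anchor = barcode[-ANCHOR_LEN:]
        if set(anchor) == {"N"}:
            continue
        barcodes.append(barcode)
        inserts.append(insert)
    assignment = greedy_cluster(barcodes, max_mismatch)
    bins: dict[int, list[str]] = {}
    for barcode, insert in zip(barcodes, inserts):
        bins.setdefault(assignment[barcode], []).append(insert)
    out = []
    for members in bins.values():
        consensus = collapse(members, min_reads, agreement)
        if consensus is not None:
            out.append((consensus, len(members)))
    return Counter(out)
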