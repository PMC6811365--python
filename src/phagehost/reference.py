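"""Deposited reference genomes (optional validation data).

The genomes this pipeline was validated against are public: the complete
*Fonsibacter* host genome (Fonsibacter_30_26), its prophage
(uv-Fonsiphage-EPL) and related lytic phage genomes, deposited under NCBI
BioProject PRJNA552483 and mirrored on figshare
(https://figshare.com/articles/Fonsibacter_and_phages_genomes/9867587).
They are not bundled: download them once into ``data/reference/`` as
``<name>.fasta`` (or ``.fna``) to enable the validation checks.

Expected statistics of the deposited assemblies:
"""

from __future__ import annotations

from pathlib import Path

from .records import GenomeRecord, read_fasta

__all__ = ["REFERENCE_STATS", "load_reference_genome", "locate_subsequence"]

#: name -> (length bp, GC %) of the deposited assemblies
REFERENCE_STATS: dict[str, tuple[int, float]] = {
    "Fonsibacter_30_26": (1_136_868, 29.6),
    "uv-Fonsiphage-EPL": (39_413, 32.1),
    "HTVC010P-related_33_76": (35_816, 32.5),
    "HTVC010P-related_32_16": (36_457, 31.9),
    "HTVC010P-related_33_10": (36_507, 32.5),
}

DEFAULT_DIR = Path("data") / "reference"


def load_reference_genome(name: str,
                          search_dir: str | Path | None = None) -> GenomeRecord:
    """Load a deposited genome from the local reference directory.

    Raises ``FileNotFoundError`` with download instructions when the FASTA
    has not been fetched (no network access is ever attempted).
    """
    base = Path(search_dir) if search_dir else DEFAULT_DIR
    for ext in (".fasta", ".fna", ".fa"):
        path = base / f"{name}{ext}"
        if path.exists():
            recs = read_fasta(path)
            if not recs:
                raise ValueError(f"{path} contains no sequences")
            if len(recs) == 1:
                return GenomeRecord(name, recs[0].seq, recs[0].circular)
            seq = "".join(r.seq for r in recs)
            return GenomeRecord(name, seq)
    raise FileNotFoundError(
        f"reference genome {name!r} not found under {base}/ — download it "
        "from NCBI BioProject PRJNA552483 (or the figshare mirror, "
        "https://figshare.com/articles/Fonsibacter_and_phages_genomes/9867587) "
        f"and save it as {base / (name + '.fasta')}"
    )


def locate_subsequence(host: GenomeRecord, query: GenomeRecord,
                       anchor: int = 500, step: int = 2_000,
                       ) -> tuple[int, int] | None:
    """Approximate location of ``query`` inside ``host`` via exact anchors.

    Slides ``anchor``-bp chunks of the query every ``step`` bp and
    collects exact matches in the host; returns the spanned host interval
    (padded by one anchor) or ``None`` when fewer than two anchors hit.
    Useful to turn a known phage genome into a region hint for att-site
    search on its host scaffold.
    """
    hits = []
    for off in range(0, len(query.seq) - anchor + 1, step):
        chunk = query.seq[off: off + anchor]
        pos = host.seq.find(chunk)
        if pos >= 0:
            hits.append(pos)
    if len(hits) < 2:
        return None
    lo, hi = min(hits), max(hits) + anchor
    pad = step + anchor
    return max(0, lo - pad), min(len(host.seq), hi + pad)
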