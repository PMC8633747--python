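"""Upstream ORF detection and classification in 5'-UTRs.

Every ATG in the spliced 5'-UTR starts a potential upstream reading frame.
Reading from that uATG through the UTR and on into the CDS:

* class 3 — the frame meets a stop codon entirely within the 5'-UTR (a
  complete upstream ORF);
* class 1 — no stop before the annotated start and the uATG is in frame with
  it (a potential N-terminal extension of the main product);
* class 2 — the uATG is out of frame and the first stop falls inside the
  coding sequence (or is never reached).

Classification operates on the spliced transcript because reading frame is a
transcript property; pass unspliced strings to the same functions for
annotation-free use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class uORFRecord:
    gene_id: str
    u_class: int
    uatg_offset: int          # bp from 5'-UTR start, spliced coordinates
    frame_vs_main: int        # (main ATG offset - uATG offset) mod 3
    stop_offset: int | None   # transcript offset of the stop codon, if reached
    kozak_flag: bool


def has_kozak_context(transcript: str, atg_offset: int) -> bool:
    """Configurable initiation-context check: purine at -3 or G at +4.

    Informational only; the motif convention is declared, not validated.
    """
    ok = False
    if atg_offset >= 3 and transcript[atg_offset - 3] in "AG":
        ok = True
    if atg_offset + 3 < len(transcript) and transcript[atg_offset + 3] == "G":
        ok = True
    return ok


def find_uorfs(utr5: str, cds: str, gene_id: str = "") -> list[uORFRecord]:
    """Classify every ATG in the 5'-UTR; one record per uATG."""
    utr5 = utr5.upper()
    cds = cds.upper()
    if not utr5:
        return []
    if cds and not cds.startswith("ATG"):
        raise ValueError(f"{gene_id or 'CDS'} does not start with ATG")
    transcript = utr5 + cds
    main_atg = len(utr5)
    records: list[uORFRecord] = []
    for i in range(len(utr5) - 2):
        if utr5[i:i + 3] != "ATG":
            continue
        frame = (main_atg - i) % 3
        stop_offset: int | None = None
        for j in range(i, len(transcript) - 2, 3):
            if transcript[j:j + 3] in STOPS:
                stop_offset = j
                break
        if stop_offset is not None and stop_offset + 3 <= main_atg:
            u_class = 3
        elif frame == 0:
            u_class = 1
            stop_offset = None  # reads through into the main ORF
        else:
            u_class = 2
        records.append(uORFRecord(
            gene_id=gene_id, u_class=u_class, uatg_offset=i,
            frame_vs_main=frame, stop_offset=stop_offset,
            kozak_flag=has_kozak_context(transcript, i)))
    return records


def dataset_uorf_summary(records_per_gene: dict[str, list[uORFRecord]]) -> pd.DataFrame:
    """Per-class fraction of genes with >= 1 uORF of that class.

    Genes may count toward several classes; a gene with many uORFs of one
    class counts once for it.  Returns an explicit zero-gene marker row when
    the input is empty.
    """
    n_genes = len(records_per_gene)
    rows = []
    for u_class in (1, 2, 3):
        n_with = sum(1 for recs in records_per_gene.values()
                     if any(r.u_class == u_class for r in recs))
        rows.append({
            "u_class": u_class,
            "genes_with_uorf": n_with,
            "fraction": n_with / n_genes if n_genes else float("nan"),
            "n_genes": n_genes,
        })
    return pd.DataFrame(rows)


def records_to_frame(records: list[uORFRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "class": r.u_class, "uatg_offset": r.uatg_offset,
        "frame_vs_main": r.frame_vs_main,
        "stop_offset": "" if r.stop_offset is None else r.stop_offset,
        "kozak_flag": r.kozak_flag,
    } for r in records])
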