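"""Fetch the published reference sequences used by the acceptance tests.

Requires network access to NCBI.  Downloads into ``data/reference/``:

* ``PA4554.fasta`` — the Pseudomonas aeruginosa PAO1 PilY1 protein.
* ``fig1_panel.fasta`` — the fifteen published PilY1/PilC reference
  proteins (Neisseria PilC1/2, P. aeruginosa PilY1, Kingella PilC1/2,
  Xylella PilY1.1-1.3, Legionella PilY1, Myxococcus PilY1.1-1.3,
  Acidithiobacillus PilY1).

Two further inputs cannot be scripted because they come from a
publication's supplementary tables rather than from stable sequence
accessions, and must be assembled manually:

* ``pily1_150.fasta`` — the 150 Myxococcota PilY1 proteins.
* ``clade_members.tsv`` — two columns (protein id, clade label) mapping
  each of those proteins to its clade.

Each printed identifier is resolved with an NCBI protein-database search
(several are locus tags, not accessions) and the first hit is fetched;
review the log to confirm the resolved records are the intended ones.
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
OUTDIR = Path(__file__).resolve().parent.parent / "data" / "reference"

PA4554 = ["PA4554"]
FIG1_PANEL = [
    "CAM09357", "CAM09680",                      # N. meningitidis PilC1/2
    "WP_353124200.1", "WP_172763930.1",          # N. gonorrhoeae PilC1/2
    "PA4554",                                    # P. aeruginosa PilY1
    "CRZ20459", "CRZ19786",                      # K. kingae PilC1/2
    "PD1611", "PD0502", "PD0023",                # X. fastidiosa PilY1.1-3
    "Q5ZXV3",                                    # L. pneumophila PilY1
    "MXAN_0362", "MXAN_1020", "MXAN_1365",       # M. xanthus PilY1.1-3
    "QFX95975",                                  # A. thiooxidans PilY1
]


def _get(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


def resolve(term: str) -> str | None:
    query = urllib.parse.quote(f"{term}")
    url = f"{EUTILS}/esearch.fcgi?db=protein&term={query}&retmax=1"
    text = _get(url).decode()
    if "<Id>" not in text:
        return None
    return text.split("<Id>")[1].split("</Id>")[0]


def fetch_fasta(uid: str) -> str:
    url = f"{EUTILS}/efetch.fcgi?db=protein&id={uid}&rettype=fasta&retmode=text"
    return _get(url).decode()


def fetch_set(identifiers: list[str], out_path: Path) -> None:
    entries = []
    for ident in identifiers:
        uid = resolve(ident)
        if uid is None:
            print(f"  !! {ident}: no protein-database hit", file=sys.stderr)
            continue
        fasta = fetch_fasta(uid).strip()
        header, _, body = fasta.partition("\n")
        print(f"  {ident} -> {header[1:60]}")
        entries.append(f">{ident} {header[1:]}\n{body}\n")
        time.sleep(0.4)  # NCBI rate limit
    out_path.write_text("".join(entries))
    print(f"wrote {out_path} ({len(entries)} records)")


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    print("fetching PA4554 ...")
    fetch_set(PA4554, OUTDIR / "PA4554.fasta")
    print("fetching the 15-protein reference panel ...")
    fetch_set(FIG1_PANEL, OUTDIR / "fig1_panel.fasta")
    print("NOTE: pily1_150.fasta and clade_members.tsv must be assembled "
          "manually from the publication's supplementary material.")


if __name__ == "__main__":
    main()
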