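"""Identifier normalization shared by the reference index and the annotator.

All matching in matrisomekit happens on *normalized keys*. A raw cell value
or reference alias is trimmed, upper-cased, and stripped of decorations that
carry no gene/protein identity:

* UniProt isoform suffixes (``P02452-2`` -> ``P02452``);
* Ensembl-style trailing versions (``ENSG00000108821.5`` -> ``ENSG00000108821``).

Multi-identifier cells are split on ``;``, ``,`` and ``|``, preserving the
order in which sub-identifiers appear — downstream matching gives precedence
to the first sub-identifier that hits the reference (the proteomics
"leading protein" convention).

Hyphenated gene symbols (``emb-9``, ``sdn-1`` and other nematode names) are
deliberately left intact: the isoform rule only fires when the prefix looks
like a UniProt accession (letter, digit, alphanumerics, digit).
"""

from __future__ import annotations

import re

_SPLIT = re.compile(r"[;,|]")

# Prefix must look like a UniProt accession before "-<n>" is treated as an
# isoform suffix; gene symbols such as EMB-9 never match (2nd char not a digit).
_UNIPROT_ISOFORM = re.compile(r"^([A-Z][0-9][A-Z0-9]{3,8}[0-9])-\d+$")

# Ensembl gene/transcript/protein accession with a trailing ".version".
_ENSEMBL_VERSION = re.compile(r"^(ENS[A-Z]{0,5}[GTP]\d{6,})\.\d+$")


def normalize_token(token: str) -> str:
    """Normalize a single identifier token to its matching key.

    Returns the empty string when the token is blank. Never splits.
    """
    key = token.strip().upper()
    if not key:
        return ""
    m = _UNIPROT_ISOFORM.match(key)
    if m:
        return m.group(1)
    m = _ENSEMBL_VERSION.match(key)
    if m:
        return m.group(1)
    return key


def normalize_identifier(raw: str) -> list[str]:
    """Normalize a raw cell value into an ordered list of matching keys.

    Splits multi-identifier cells on ``;``, ``,`` and ``|``; blank tokens are
    dropped; an empty/blank input yields an empty list.
    """
    if raw is None:
        return []
    keys = []
    for token in _SPLIT.split(str(raw)):
        key = normalize_token(token)
        if key:
            keys.append(key)
    return keys
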