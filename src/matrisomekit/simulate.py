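"""Synthetic omics fixture generation.

Emulates the tabular inputs the annotation engine is designed for, without
shipping any real dataset:

* ``proteomics`` — a label-free proteomics results table: an identifier
  column mixing gene symbols and UniProt accessions (in assorted letter
  case, occasionally as multi-ID cells), per-sample integer spectral-count
  columns, a plain-number molecular-mass column (kDa, no unit appended) and
  a percent-formatted identification-probability column. The last two
  reproduce the classic tabulation pitfalls: a mass column is numerically
  coercible (and hence tabulated, relevant or not) while a percent column
  is not coercible and must be excluded.
* ``expression`` — gene symbols with per-sample continuous abundance
  columns (log-normal, dot decimals).
* ``exome-counts`` — gene symbols with an integer mutation-count column and
  a categorical subtype column, convenient for alluvial (matriflow) charts.

Matrisome rows draw their identifiers from a loaded reference (any alias,
any namespace); the remaining rows get decoy identifiers guaranteed absent
from the reference. All generation is deterministic under a seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .reference import MatrisomeReference, bundled_tag_for_species, load_reference
from .identifiers import normalize_token
from .tabular_io import OmicsTable, write_csv

_CASE_STYLES = ("asis", "upper", "lower", "title")

FIXTURE_KINDS = ("proteomics", "expression", "exome-counts")


def _alias_pool(ref: MatrisomeReference) -> list[str]:
    pool = []
    for entry in ref.entries:
        for _, alias in entry.aliases():
            if alias:
                pool.append(alias)
    return pool


def _decoy(rng: np.random.Generator, index) -> str:
    """A plausible-looking identifier guaranteed absent from the reference."""
    for _ in range(100):
        letters = "".join(rng.choice(list("ABCDEFGHIKLMNRSTUVWXYZ"), size=3))
        cand = f"{letters}{rng.integers(1, 99)}"
        if normalize_token(cand) not in index:
            return cand
    raise RuntimeError("could not generate a decoy identifier")  # pragma: no cover


def _styled(rng: np.random.Generator, alias: str) -> str:
    style = _CASE_STYLES[rng.integers(0, len(_CASE_STYLES))]
    if style == "upper":
        return alias.upper()
    if style == "lower":
        return alias.lower()
    if style == "title":
        return alias.title()
    return alias


def _identifiers(rng: np.random.Generator, ref: MatrisomeReference, n_rows: int,
                 matrisome_fraction: float) -> list[str]:
    if not 0.0 <= matrisome_fraction <= 1.0:
        raise ParameterError("matrisome_fraction must be between 0 and 1")
    pool = _alias_pool(ref)
    n_matrisome = int(round(n_rows * matrisome_fraction))
    is_matrisome = np.zeros(n_rows, dtype=bool)
    is_matrisome[:n_matrisome] = True
    rng.shuffle(is_matrisome)
    ids = []
    for hit in is_matrisome:
        if hit:
            ident = _styled(rng, pool[rng.integers(0, len(pool))])
            if rng.random() < 0.15:  # multi-ID cell; leading entry decides
                ident = f"{ident};{_decoy(rng, ref.index)}"
        else:
            ident = _decoy(rng, ref.index)
        ids.append(ident)
    return ids


def generate_proteomics_table(
    n_rows: int = 200,
    n_samples: int = 3,
    matrisome_fraction: float = 0.3,
    species: str = "human",
    reference: MatrisomeReference | str = "test-human",
    seed: int | np.random.Generator = 0,
) -> OmicsTable:
    """Generate a label-free proteomics results table.

    Spectral counts are negative-binomial (dispersed counts around a mean
    of ~18 spectra per protein and sample); molecular masses are uniform on
    10–300 kDa with one decimal; identification probabilities are drawn
    from typical filtered-search values and formatted as percentages.
    """
    if n_rows <= 0:
        raise ParameterError("n_rows must be positive")
    if n_samples <= 0:
        raise ParameterError("n_samples must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = reference if isinstance(reference, MatrisomeReference) else load_reference(
        reference, species=species)
    ids = _identifiers(rng, ref, n_rows, matrisome_fraction)
    data: dict[str, list[str]] = {"Protein IDs": ids}
    for s in range(1, n_samples + 1):
        counts = rng.negative_binomial(2, 0.1, size=n_rows)
        data[f"Total Spectra Sample {s}"] = [str(int(c)) for c in counts]
    mass = rng.uniform(10.0, 300.0, size=n_rows)
    data["Molecular Weight (kDa)"] = [f"{m:.1f}" for m in mass]
    probs = rng.choice(["100%", "99%", "98%", "95%"], size=n_rows,
                       p=[0.55, 0.3, 0.1, 0.05])
    data["Identification Probability"] = [str(p) for p in probs]
    df = pd.DataFrame(data, dtype=object)
    return OmicsTable(df=df, provenance={"source": "simulate.proteomics",
                                         "species": ref.species})


def generate_expression_table(
    n_rows: int = 200,
    n_samples: int = 4,
    matrisome_fraction: float = 0.3,
    species: str = "human",
    reference: MatrisomeReference | str = "test-human",
    seed: int | np.random.Generator = 0,
) -> OmicsTable:
    """Generate a bulk-expression-style table (log-normal abundances)."""
    if n_rows <= 0 or n_samples <= 0:
        raise ParameterError("n_rows and n_samples must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = reference if isinstance(reference, MatrisomeReference) else load_reference(
        reference, species=species)
    ids = _identifiers(rng, ref, n_rows, matrisome_fraction)
    data: dict[str, list[str]] = {"Gene": ids}
    for s in range(1, n_samples + 1):
        expr = rng.lognormal(mean=2.0, sigma=1.0, size=n_rows)
        data[f"TPM Sample {s}"] = [f"{v:.3f}" for v in expr]
    return OmicsTable(df=pd.DataFrame(data, dtype=object),
                      provenance={"source": "simulate.expression", "species": ref.species})


def generate_exome_counts_table(
    n_rows: int = 200,
    n_samples: int = 2,  # number of subtype groups
    matrisome_fraction: float = 0.3,
    species: str = "human",
    reference: MatrisomeReference | str = "test-human",
    seed: int | np.random.Generator = 0,
) -> OmicsTable:
    """Generate an exome-style table: mutation counts plus a subtype column."""
    if n_rows <= 0 or n_samples <= 0:
        raise ParameterError("n_rows and n_samples must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = reference if isinstance(reference, MatrisomeReference) else load_reference(
        reference, species=species)
    ids = _identifiers(rng, ref, n_rows, matrisome_fraction)
    subtypes = [f"Subtype {chr(65 + int(i))}" for i in rng.integers(0, n_samples, size=n_rows)]
    counts = rng.poisson(5.0, size=n_rows)
    df = pd.DataFrame({"Gene": ids,
                       "Mutation Count": [str(int(c)) for c in counts],
                       "Subtype": subtypes}, dtype=object)
    return OmicsTable(df=df, provenance={"source": "simulate.exome", "species": ref.species})


_GENERATORS = {
    "proteomics": generate_proteomics_table,
    "expression": generate_expression_table,
    "exome-counts": generate_exome_counts_table,
}


def make_fixture(
    kind: str,
    out_dir: str | Path,
    n_rows: int = 200,
    n_samples: int = 3,
    matrisome_fraction: float = 0.3,
    species: str = "human",
    reference: MatrisomeReference | str | None = None,
    seed: int = 0,
) -> list[Path]:
    """Write a synthetic fixture of the given kind to ``out_dir``.

    Byte-identical output under the same seed and parameters. Returns the
    list of written paths (one CSV).
    """
    if kind not in _GENERATORS:
        raise ParameterError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    if reference is None:
        reference = bundled_tag_for_species(species)
    table = _GENERATORS[kind](n_rows=n_rows, n_samples=n_samples,
                              matrisome_fraction=matrisome_fraction,
                              species=species, reference=reference, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{kind.replace('-', '_')}_fixture.csv"
    write_csv(table, path)
    return [path]
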