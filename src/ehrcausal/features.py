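"""Confounder representations: high-dimensional one-hot and averaged embeddings.

Two ways of encoding a patient's pre-index state for the propensity model:

* one-hot: one binary indicator per distinct concept code plus one per
  demographic level (10-year age bins, gender, race, ethnicity, zip3);
  presence, not counts;
* embedding: the componentwise mean of the concept vectors of the person's
  distinct codes, with raw age and one-hot categorical demographics appended
  so both propensity models condition on the same confounder set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import CohortPair
from .synth.embeddings import EmbeddingTable

logger = logging.getLogger(__name__)

DEMO_FIELDS = ["gender", "race", "ethnicity", "zip3"]


def age_bin_key(age: int) -> str:
    lo = 10 * (int(age) // 10)
    return f"age:{lo}-{lo + 9}"


@dataclass
class Vocabulary:
    """Ordered covariate keys; codes first, then demographic levels."""

    keys: list[str]

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("vocabulary keys must be unique")
        self.index = {k: i for i, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: str) -> bool:
        return key in self.index

    @property
    def code_keys(self) -> list[str]:
        return [k for k in self.keys if ":" not in k]

    @property
    def demographic_keys(self) -> list[str]:
        return [k for k in self.keys if ":" in k]

    def drop(self, keys) -> "Vocabulary":
        """New vocabulary without ``keys`` (used to keep a negative-control
        outcome out of its own confounder set)."""
        drop = set(keys)
        return Vocabulary([k for k in self.keys if k not in drop])


def build_vocabulary(code_events: pd.DataFrame, persons: pd.DataFrame) -> Vocabulary:
    """One key per distinct observed code and per observed demographic level."""
    keys = sorted(code_events["code"].unique()) if len(code_events) else []
    keys += sorted({age_bin_key(a) for a in persons["age"]})
    for field in DEMO_FIELDS:
        vals = persons[field].dropna().astype(str)
        vals = vals[vals.str.strip() != ""]
        keys += [f"{field}:{v}" for v in sorted(vals.unique())]
    return Vocabulary(keys)


def _demo_keys_for(row) -> list[str]:
    keys = [age_bin_key(row["age"])]
    for field in DEMO_FIELDS:
        v = row[field]
        if pd.notna(v) and str(v).strip() != "":
            keys.append(f"{field}:{v}")
    return keys


def one_hot_encode(person_row, person_codes, vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse 1 x |vocab| indicator vector for one person.

    Code multiplicity is collapsed to presence. Codes absent from the
    vocabulary are ignored with a warning (transform-time novelty).
    """
    cols = []
    unseen = []
    for code in set(person_codes):
        if code in vocab:
            cols.append(vocab.index[code])
        else:
            unseen.append(code)
    if unseen:
        logger.warning("ignoring %d codes absent from vocabulary: %s", len(unseen), unseen[:5])
    for key in _demo_keys_for(person_row):
        if key in vocab:
            cols.append(vocab.index[key])
    data = np.ones(len(cols))
    return sp.csr_matrix((data, (np.zeros(len(cols), dtype=int), cols)), shape=(1, len(vocab)))


def embed_patient(codes_i, table: EmbeddingTable, collapse_duplicates: bool = True) -> np.ndarray:
    """Average the embedding vectors of a person's codes (componentwise mean).

    Duplicate occurrences are collapsed to distinct codes by default — the
    history is treated as a set. Codes without a vector are dropped; if none
    remain the patient is unembeddable and the caller decides exclusion.
    """
    codes = [c for c in codes_i if c in table]
    if collapse_duplicates:
        codes = sorted(set(codes))
    if not codes:
        raise ValueError("patient has no codes representable in the embedding table")
    return np.mean([table[c] for c in codes], axis=0)


def _cohort_order(cohort: CohortPair) -> tuple[list, np.ndarray]:
    ids = sorted(cohort.treated_ids) + sorted(cohort.comparator_ids)
    labels = np.concatenate(
        [np.ones(len(cohort.treated_ids), dtype=int), np.zeros(len(cohort.comparator_ids), dtype=int)]
    )
    return ids, labels


def _demo_key_frame(demo: pd.DataFrame) -> pd.DataFrame:
    """Per-person demographic keys, one column per field (NaN where missing)."""
    lo = demo["age"].astype(int).floordiv(10).mul(10)
    out = pd.DataFrame(index=demo.index)
    out["age"] = "age:" + lo.astype(str) + "-" + (lo + 9).astype(str)
    for field in DEMO_FIELDS:
        v = demo[field].astype("string")
        v = v.where(v.notna() & (v.str.strip() != ""))
        out[field] = field + ":" + v
    return out


def build_design_matrices(
    cohort: CohortPair,
    mode: str,
    persons: pd.DataFrame,
    code_events: pd.DataFrame,
    vocab: Vocabulary,
    table: EmbeddingTable | None = None,
):
    """Design matrix and treatment labels for one contrast.

    Rows follow a stored person-id order (sorted treated, then sorted
    comparator). ``mode="one_hot"`` gives a sparse binary matrix over the
    vocabulary; ``mode="embedding"`` gives a dense matrix of the averaged
    code vectors with raw age and one-hot categorical demographics appended.

    Returns ``(matrix, labels, person_ids)``; in embedding mode persons with
    no representable codes are dropped from all three outputs and counted in
    the log. Batch results match the per-person :func:`one_hot_encode` /
    :func:`embed_patient` operations row for row.
    """
    ids, labels = _cohort_order(cohort)
    pers = persons.set_index("person_id")
    n_missing = len(set(ids) - set(pers.index))
    if n_missing:
        raise ValueError(f"{n_missing} cohort members missing from persons table")
    row_of = {pid: i for i, pid in enumerate(ids)}
    ev = code_events[code_events["person_id"].isin(row_of)]
    demo = pers.loc[ids]
    demo_keys_frame = _demo_key_frame(demo)

    if mode == "one_hot":
        pairs = ev[["person_id", "code"]].drop_duplicates()
        known = pairs["code"].isin(vocab.index)
        n_unseen = int((~known).sum())
        if n_unseen:
            logger.warning("ignoring %d events with codes absent from vocabulary", n_unseen)
        pairs = pairs[known]
        rows = [pairs["person_id"].map(row_of).to_numpy()]
        cols = [pairs["code"].map(vocab.index).to_numpy()]
        all_rows = np.arange(len(ids))
        for field in demo_keys_frame.columns:
            col = demo_keys_frame[field].map(vocab.index)
            ok = col.notna().to_numpy()
            rows.append(all_rows[ok])
            cols.append(col.to_numpy(dtype=float)[ok].astype(int))
        rows_arr = np.concatenate(rows)
        cols_arr = np.concatenate(cols)
        X = sp.csr_matrix(
            (np.ones(len(rows_arr)), (rows_arr, cols_arr)), shape=(len(ids), len(vocab))
        )
        return X, labels, np.array(ids)

    if mode == "embedding":
        if table is None:
            raise ValueError("embedding mode requires an EmbeddingTable")
        # mean embedding over each person's distinct representable codes
        pairs = ev[["person_id", "code"]].drop_duplicates()
        pairs = pairs[pairs["code"].isin(table.index)]
        p_rows = pairs["person_id"].map(row_of).to_numpy()
        c_rows = pairs["code"].map(table.index).to_numpy()
        indic = sp.csr_matrix(
            (np.ones(len(p_rows)), (p_rows, c_rows)),
            shape=(len(ids), len(table.codes)),
        )
        sums = indic @ table.vectors
        counts = np.bincount(p_rows, minlength=len(ids)).astype(float)
        embeddable = counts > 0
        n_dropped = int((~embeddable).sum())
        if n_dropped:
            logger.warning("dropped %d unembeddable patients (no representable codes)", n_dropped)
        if not embeddable.any():
            raise ValueError("no embeddable patients in cohort")
        emb = sums[embeddable] / counts[embeddable, None]

        demo_keys = [k for k in vocab.demographic_keys if not k.startswith("age:")]
        demo_index = {k: i for i, k in enumerate(demo_keys)}
        demo_block = np.zeros((len(ids), 1 + len(demo_keys)))
        demo_block[:, 0] = demo["age"].to_numpy(dtype=float)
        all_rows = np.arange(len(ids))
        for field in DEMO_FIELDS:
            col = demo_keys_frame[field].map(demo_index)
            ok = col.notna().to_numpy()
            demo_block[all_rows[ok], 1 + col.to_numpy(dtype=float)[ok].astype(int)] = 1.0
        X = np.hstack([emb, demo_block[embeddable]])
        return X, labels[embeddable], np.array(ids)[embeddable]

    raise ValueError(f"unknown mode {mode!r}")


def save_matrix(matrix, path) -> None:
    """Cache a design matrix: sparse -> triplet text (row,col,value with a
    shape header), dense -> plain delimited rows."""
    if sp.issparse(matrix):
        coo = matrix.tocoo()
        with open(path, "w") as fh:
            fh.write(f"# sparse {coo.shape[0]} {coo.shape[1]}\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r},{c},{v:g}\n")
    else:
        np.savetxt(path, np.asarray(matrix), delimiter=",")


def load_matrix(path):
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# sparse"):
            _, _, nr, nc = first.split()
            rows, cols, vals = [], [], []
            for line in fh:
                r, c, v = line.split(",")
                rows.append(int(r))
                cols.append(int(c))
                vals.append(float(v))
            return sp.csr_matrix((vals, (rows, cols)), shape=(int(nr), int(nc)))
    return np.loadtxt(path, delimiter=",", ndmin=2)
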