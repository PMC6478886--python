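"""Independent brute-force oracles used to validate the pipeline.

Sums of squares are computed from marginal means via the classical
full-partition identities (balanced data), entirely outside the package's
fitting machinery; F assignments are hard-coded from the mixed-model
error-term tables.
"""

import numpy as np


def mixed_3way_oracle(frame, w1="Location", w2="Texture", between="Drink",
                      subject="Subject", value="value"):
    """Full-decomposition mean squares and F-ratios for a balanced design
    with two within factors and one between factor."""
    df = frame
    a = df[w1].nunique()
    b = df[w2].nunique()
    mu = df[value].mean()
    mA = df.groupby(w1)[value].mean()
    mB = df.groupby(w2)[value].mean()
    mC = df.groupby(between)[value].mean()
    mAB = df.groupby([w1, w2])[value].mean()
    mAC = df.groupby([w1, between])[value].mean()
    mBC = df.groupby([w2, between])[value].mean()
    mABC = df.groupby([w1, w2, between])[value].mean()
    mS = df.groupby(subject)[value].mean()
    mSA = df.groupby([subject, w1])[value].mean()
    mSB = df.groupby([subject, w2])[value].mean()
    sg = df.drop_duplicates(subject).set_index(subject)[between]
    nsub_g = df.groupby(between)[subject].nunique()
    Nsub = int(nsub_g.sum())
    g = len(nsub_g)

    SS = {}
    SS["A"] = float(((mA - mu) ** 2).sum() * b * Nsub)
    SS["B"] = float(((mB - mu) ** 2).sum() * a * Nsub)
    SS["C"] = float(sum((mC[k] - mu) ** 2 * nsub_g[k] * a * b
                        for k in mC.index))
    SS["AB"] = float(sum((mAB[(i, j)] - mA[i] - mB[j] + mu) ** 2 * Nsub
                         for i, j in mAB.index))
    SS["AC"] = float(sum((mAC[(i, k)] - mA[i] - mC[k] + mu) ** 2
                         * b * nsub_g[k] for i, k in mAC.index))
    SS["BC"] = float(sum((mBC[(j, k)] - mB[j] - mC[k] + mu) ** 2
                         * a * nsub_g[k] for j, k in mBC.index))
    SS["ABC"] = float(sum(
        (mABC[(i, j, k)] - mAB[(i, j)] - mAC[(i, k)] - mBC[(j, k)]
         + mA[i] + mB[j] + mC[k] - mu) ** 2 * nsub_g[k]
        for i, j, k in mABC.index))
    SS["S"] = float(sum((mS[s] - mC[sg[s]]) ** 2 * a * b for s in mS.index))
    SS["SA"] = float(sum(
        (mSA[(s, i)] - mS[s] - mAC[(i, sg[s])] + mC[sg[s]]) ** 2 * b
        for s, i in mSA.index))
    SS["SB"] = float(sum(
        (mSB[(s, j)] - mS[s] - mBC[(j, sg[s])] + mC[sg[s]]) ** 2 * a
        for s, j in mSB.index))
    SS["total"] = float(((df[value] - mu) ** 2).sum())
    SS["E"] = SS["total"] - sum(SS[k] for k in
                                ("A", "B", "C", "AB", "AC", "BC", "ABC",
                                 "S", "SA", "SB"))
    dfree = {
        "A": a - 1, "B": b - 1, "C": g - 1,
        "AB": (a - 1) * (b - 1), "AC": (a - 1) * (g - 1),
        "BC": (b - 1) * (g - 1), "ABC": (a - 1) * (b - 1) * (g - 1),
        "S": Nsub - g, "SA": (Nsub - g) * (a - 1),
        "SB": (Nsub - g) * (b - 1), "E": (Nsub - g) * (a - 1) * (b - 1),
    }
    MS = {k: SS[k] / dfree[k] for k in dfree}
    F = {
        "A": MS["A"] / MS["SA"],
        "B": MS["B"] / MS["SB"],
        "C": MS["C"] / MS["S"],
        "AB": MS["AB"] / MS["E"],
        "AC": MS["AC"] / MS["SA"],
        "BC": MS["BC"] / MS["SB"],
        "ABC": MS["ABC"] / MS["E"],
    }
    return {"SS": SS, "df": dfree, "MS": MS, "F": F}


def mixed_2way_ss_matrix(Y, g, n, a):
    """Vectorised full-partition sums of squares for a balanced two-way
    mixed design (one within factor, ``g`` groups of ``n`` subjects).

    ``Y`` has one observation per row in canonical order (group-major,
    subject-major, within level fastest) and one replicate per column.
    Returns dict of SS arrays over columns.
    """
    R = Y.reshape(g, n, a, -1)
    mu = R.mean(axis=(0, 1, 2))
    mA = R.mean(axis=(0, 1))          # a x reps
    mG = R.mean(axis=(1, 2))          # g x reps
    mAG = R.mean(axis=1)              # g x a x reps
    mS = R.mean(axis=2)               # g x n x reps
    SS_A = (n * g) * ((mA - mu) ** 2).sum(axis=0)
    SS_B = (n * a) * ((mG - mu) ** 2).sum(axis=0)
    SS_AB = n * ((mAG - mG[:, None] - mA[None, :] + mu) ** 2).sum(axis=(0, 1))
    SS_S = a * ((mS - mG[:, None]) ** 2).sum(axis=(0, 1))
    SS_tot = ((R - mu) ** 2).sum(axis=(0, 1, 2))
    SS_E = SS_tot - SS_A - SS_B - SS_AB - SS_S
    return {"A": SS_A, "B": SS_B, "AB": SS_AB, "S": SS_S, "E": SS_E,
            "total": SS_tot}
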