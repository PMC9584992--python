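"""Independent oracle: evaluate the 12 published eGFR equations on 5 panel
patients with explicit scalar arithmetic (no gfragree imports).  Output frozen
into tests/data/formula_panel.csv.  Absolute ml/min values (indexed equations
un-adjusted with Du Bois BSA)."""
import math

patients = [
    # id, age, sex, weight, height, scr(mg/dL), cysc(mg/L)
    ("P1", 35, "male", 85, 182, 0.9, 0.85),
    ("P2", 52, "female", 64, 160, 1.3, 1.40),
    ("P3", 68, "male", 78, 175, 2.8, 2.60),
    ("P4", 29, "female", 55, 152, 0.6, 0.70),
    ("P5", 45, "male", 95, 178, 5.5, 3.90),
]


def bsa(w, h):
    return 0.007184 * w**0.425 * h**0.725


def amdrd(age, male, scr):
    v = 175 * scr**-1.154 * age**-0.203
    if not male:
        v *= 0.742
    return v


def ckdepi_cr(age, male, scr):
    if male:
        k, a = 0.9, -0.411
        sexf = 1.0
    else:
        k, a = 0.7, -0.329
        sexf = 1.018
    return 141 * min(scr / k, 1) ** a * max(scr / k, 1) ** -1.209 * 0.993**age * sexf


def ckdepi_cy(age, male, cys):
    v = 133 * min(cys / 0.8, 1) ** -0.499 * max(cys / 0.8, 1) ** -1.328 * 0.996**age
    if not male:
        v *= 0.932
    return v


def ckdepi_crcy(age, male, scr, cys):
    if male:
        k, a = 0.9, -0.207
        sexf = 1.0
    else:
        k, a = 0.7, -0.248
        sexf = 0.969
    return (
        135 * min(scr / k, 1) ** a * max(scr / k, 1) ** -0.601
        * min(cys / 0.8, 1) ** -0.375 * max(cys / 0.8, 1) ** -0.711
        * 0.995**age * sexf
    )


def cg(age, male, scr, w):
    v = (140 - age) * w / (72 * scr)
    if not male:
        v *= 0.85
    return v


def fas_agef(age):
    return 0.988 ** (age - 40) if age > 40 else 1.0


def fas_cr(age, male, scr):
    q = 0.90 if male else 0.70
    return 107.3 / (scr / q) * fas_agef(age)


def fas_cy(age, cys):
    q = 0.82 if age < 70 else 0.95
    return 107.3 / (cys / q) * fas_agef(age)


def fas_crcy(age, male, scr, cys):
    qcr = 0.90 if male else 0.70
    qcy = 0.82 if age < 70 else 0.95
    return 107.3 / (0.5 * scr / qcr + 0.5 * cys / qcy) * fas_agef(age)


def lmrev(age, male, scr):
    p = scr * 88.4
    if male:
        x = 2.56 + 0.00968 * (180 - p) if p < 180 else 2.56 - 0.926 * math.log(p / 180)
    else:
        x = 2.50 + 0.0121 * (150 - p) if p < 150 else 2.50 - 0.926 * math.log(p / 150)
    return math.exp(x - 0.0158 * age + 0.438 * math.log(age))


def capa(age, cys):
    return 130 * cys**-1.069 * age**-0.117 - 7


def hoek(cys):
    return -4.32 + 80.35 / cys


def larsson(cys):
    return 77.24 * cys**-1.2623


rows = []
for pid, age, sex, w, h, scr, cys in patients:
    male = sex == "male"
    b = bsa(w, h)
    ix = b / 1.73  # un-adjustment factor for indexed equations
    vals = {
        "aMDRD": amdrd(age, male, scr) * ix,
        "CKD-EPI-cr": ckdepi_cr(age, male, scr) * ix,
        "CKD-EPI-cy": ckdepi_cy(age, male, cys) * ix,
        "CKD-EPI-cr-cy": ckdepi_crcy(age, male, scr, cys) * ix,
        "Cockcroft-Gault": cg(age, male, scr, w),  # already absolute
        "FAS-cr": fas_cr(age, male, scr) * ix,
        "FAS-cy": fas_cy(age, cys) * ix,
        "FAS-cr-cy": fas_crcy(age, male, scr, cys) * ix,
        "Lund-Malmö (Rv)": lmrev(age, male, scr) * ix,
        "Grubb-2014 (CAPA)": capa(age, cys) * ix,
        "Hoek": hoek(cys) * ix,
        "Larsson": larsson(cys),  # absolute
    }
    rows.append((pid, age, sex, w, h, scr, cys, vals))

names = list(rows[0][7])
print("id,age,sex,weight,height,scr,cysc," + ",".join(f'"{n}"' for n in names))
for pid, age, sex, w, h, scr, cys, vals in rows:
    print(
        f"{pid},{age},{sex},{w},{h},{scr},{cys},"
        + ",".join(f"{vals[n]:.4f}" for n in names)
    )
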