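"""Published post-marketing surveillance statistics for intranasal varenicline.

Reference values from the published FAERS disproportionality analysis of
Tyrvaya (varenicline nasal spray, Q4 2021 - Q2 2024): the descriptive
characteristics counts, the per-SOC and top-50 per-PT signal tables
(ROR with 95% CI, PRR with chi-squared, EBGM with EBGM05, IC with IC025,
all printed at 2 d.p.), and the pooled time-to-onset Weibull fit.

These serve as *inputs* for replication checks: classification of
published row statistics by the positivity thresholds, and the
IC = log2(EBGM) identity of the simplified BCPNN form.
"""

from __future__ import annotations

__all__ = ["TABLE1_COUNTS", "SOC_ROWS", "PT_ROWS", "TTO_REFERENCE", "row_statistics"]

#: Descriptive characteristics: section -> {category: count}; 2178 cases total.
TABLE1_COUNTS = {
    "total": 2178,
    "sex": {"male": 257, "female": 1611, "missing": 310},
    "age": {"18-65": 227, "65-85": 368, ">85": 32, "missing": 1551},
    "country": {"United States": 2178},
    "reporter": {"consumer": 1854, "health_professional": 131, "physician": 187,
                 "pharmacist": 4, "missing": 2},
    "year": {"2021": 3, "2022": 518, "2023": 596, "2024": 1061},
}

# (event, n, ror, ror_lo, ror_hi, prr, chi2, ebgm, ebgm05, ic, ic025)
SOC_ROWS = [
    ("Skin and subcutaneous tissue disorders", 150, 0.56, 0.47, 0.66, 0.57, 50.78, 0.57, 0.50, -0.81, -2.47),
    ("General disorders and administration site conditions", 666, 0.67, 0.62, 0.73, 0.72, 91.82, 0.72, 0.67, -0.48, -2.15),
    ("Respiratory, thoracic and mediastinal disorders", 1837, 11.72, 11.08, 12.41, 7.93, 11605.08, 7.91, 7.54, 2.98, 1.32),
    ("Immune system disorders", 71, 1.24, 0.98, 1.57, 1.24, 3.27, 1.24, 1.02, 0.31, -1.36),
    ("Nervous system disorders", 326, 0.87, 0.78, 0.98, 0.88, 5.69, 0.88, 0.80, -0.18, -1.85),
    ("Gastrointestinal disorders", 231, 0.55, 0.48, 0.63, 0.57, 81.50, 0.57, 0.51, -0.81, -2.48),
    ("Psychiatric disorders", 133, 0.47, 0.39, 0.56, 0.48, 78.71, 0.48, 0.42, -1.06, -2.72),
    ("Renal and urinary disorders", 11, 0.12, 0.07, 0.23, 0.13, 67.48, 0.13, 0.08, -2.98, -4.65),
    ("Cardiac disorders", 18, 0.18, 0.12, 0.29, 0.19, 65.30, 0.19, 0.13, -2.43, -4.09),
    ("Investigations", 42, 0.13, 0.10, 0.18, 0.14, 240.71, 0.14, 0.11, -2.86, -4.53),
    ("Injury, poisoning and procedural complications", 525, 0.74, 0.68, 0.81, 0.77, 41.91, 0.77, 0.71, -0.38, -2.05),
    ("Product issues", 380, 3.88, 3.49, 4.31, 3.67, 751.43, 3.66, 3.36, 1.87, 0.21),
    ("Eye disorders", 484, 5.17, 4.71, 5.68, 4.78, 1473.93, 4.78, 4.42, 2.26, 0.59),
    ("Infections and infestations", 80, 0.25, 0.20, 0.31, 0.26, 181.52, 0.26, 0.21, -1.95, -3.62),
    ("Vascular disorders", 25, 0.26, 0.18, 0.39, 0.26, 51.96, 0.26, 0.19, -1.92, -3.58),
    ("Ear and labyrinth disorders", 52, 2.51, 1.91, 3.29, 2.49, 46.55, 2.49, 1.98, 1.32, -0.35),
    ("Musculoskeletal and connective tissue disorders", 50, 0.18, 0.13, 0.23, 0.18, 189.82, 0.18, 0.15, -2.44, -4.10),
    ("Social circumstances", 19, 0.80, 0.51, 1.26, 0.80, 0.91, 0.80, 0.55, -0.31, -1.98),
    ("Metabolism and nutrition disorders", 8, 0.08, 0.04, 0.16, 0.08, 84.07, 0.08, 0.05, -3.61, -5.28),
    ("Hepatobiliary disorders", 1, 0.02, 0.00, 0.16, 0.02, 41.38, 0.02, 0.00, -5.43, -7.09),
    ("Surgical and medical procedures", 77, 0.94, 0.75, 1.18, 0.94, 0.30, 0.94, 0.78, -0.09, -1.76),
    ("Blood and lymphatic system disorders", 2, 0.02, 0.01, 0.09, 0.02, 88.84, 0.02, 0.01, -5.51, -7.18),
]

PT_ROWS = [
    ("Sneezing", 603, 353.98, 323.67, 387.13, 312.96, 166547.77, 277.97, 257.91, 8.12, 6.45),
    ("Nasal discomfort", 213, 498.81, 429.63, 579.13, 478.37, 85053.44, 401.11, 354.00, 8.65, 6.98),
    ("Rhinorrhoea", 179, 30.29, 26.08, 35.20, 29.28, 4838.60, 28.95, 25.54, 4.86, 3.19),
    ("Throat irritation", 150, 41.98, 35.64, 49.44, 40.79, 5732.38, 40.15, 35.01, 5.33, 3.66),
    ("Epistaxis", 133, 27.89, 23.46, 33.16, 27.20, 3323.72, 26.92, 23.29, 4.75, 3.08),
    ("Cough", 127, 4.95, 4.15, 5.90, 4.85, 389.21, 4.84, 4.18, 2.28, 0.61),
    ("Headache", 119, 2.58, 2.15, 3.09, 2.54, 112.15, 2.54, 2.18, 1.34, -0.32),
    ("Eye irritation", 68, 16.26, 12.79, 20.68, 16.06, 955.20, 15.97, 13.06, 4.00, 2.33),
    ("Oropharyngeal pain", 64, 7.55, 5.90, 9.66, 7.47, 358.09, 7.45, 6.06, 2.90, 1.23),
    ("Lacrimation increased", 57, 21.79, 16.76, 28.32, 21.56, 1108.53, 21.38, 17.17, 4.42, 2.75),
    ("Eye pain", 44, 9.97, 7.40, 13.42, 9.89, 350.63, 9.86, 7.69, 3.30, 1.63),
    ("Hypersensitivity", 43, 3.04, 2.25, 4.11, 3.02, 58.36, 3.02, 2.35, 1.60, -0.07),
    ("Rhinalgia", 42, 158.92, 116.20, 217.35, 157.64, 6146.38, 148.27, 114.10, 7.21, 5.54),
    ("Ocular hyperaemia", 41, 10.63, 7.81, 14.46, 10.55, 353.29, 10.51, 8.12, 3.39, 1.73),
    ("Insomnia", 39, 2.22, 1.62, 3.04, 2.21, 25.78, 2.21, 1.69, 1.14, -0.53),
    ("Dyspnoea", 36, 0.85, 0.61, 1.18, 0.85, 0.94, 0.85, 0.65, -0.23, -1.90),
    ("Nasal congestion", 36, 6.21, 4.47, 8.62, 6.17, 155.86, 6.16, 4.68, 2.62, 0.96),
    ("Vision blurred", 36, 3.71, 2.67, 5.15, 3.69, 70.75, 3.69, 2.80, 1.88, 0.22),
    ("Burning sensation", 35, 7.29, 5.22, 10.17, 7.25, 188.04, 7.23, 5.47, 2.85, 1.19),
    ("Dizziness", 34, 0.95, 0.68, 1.33, 0.95, 0.10, 0.95, 0.71, -0.08, -1.74),
    ("Rash", 33, 0.92, 0.65, 1.30, 0.92, 0.22, 0.92, 0.69, -0.12, -1.79),
    ("Nausea", 29, 0.50, 0.34, 0.72, 0.50, 14.70, 0.50, 0.37, -1.00, -2.67),
    ("Feeling abnormal", 25, 1.49, 1.01, 2.21, 1.49, 4.02, 1.49, 1.07, 0.57, -1.09),
    ("Pain", 25, 0.37, 0.25, 0.55, 0.37, 26.63, 0.37, 0.27, -1.42, -3.09),
    ("Anxiety", 21, 1.00, 0.65, 1.53, 1.00, 0.00, 1.00, 0.70, 0.00, -1.67),
    ("Upper-airway cough syndrome", 20, 25.38, 16.33, 39.47, 25.29, 461.96, 25.05, 17.31, 4.65, 2.98),
    ("Erythema", 20, 1.44, 0.93, 2.23, 1.44, 2.66, 1.44, 0.99, 0.52, -1.14),
    ("Eye pruritus", 20, 6.18, 3.98, 9.60, 6.16, 86.33, 6.15, 4.26, 2.62, 0.95),
    ("Nasal dryness", 19, 41.43, 26.31, 65.26, 41.29, 734.73, 40.63, 27.78, 5.34, 3.68),
    ("Sinusitis", 19, 2.03, 1.29, 3.18, 2.02, 9.86, 2.02, 1.39, 1.02, -0.65),
    ("Pruritus", 18, 0.55, 0.34, 0.87, 0.55, 6.80, 0.55, 0.37, -0.87, -2.54),
    ("Drug hypersensitivity", 18, 1.36, 0.86, 2.16, 1.36, 1.71, 1.36, 0.92, 0.44, -1.22),
    ("Nasal ulcer", 17, 152.53, 93.40, 249.10, 152.03, 2403.20, 143.30, 95.06, 7.16, 5.49),
    ("Urticaria", 16, 1.32, 0.81, 2.16, 1.32, 1.26, 1.32, 0.88, 0.40, -1.26),
    ("Palpitations", 16, 1.99, 1.22, 3.25, 1.99, 7.84, 1.99, 1.32, 0.99, -0.68),
    ("Visual impairment", 16, 1.50, 0.92, 2.45, 1.50, 2.63, 1.49, 0.99, 0.58, -1.09),
    ("Dysphonia", 16, 3.32, 2.03, 5.42, 3.31, 25.80, 3.31, 2.19, 1.73, 0.06),
    ("Abnormal dreams", 15, 13.32, 8.01, 22.13, 13.28, 169.46, 13.21, 8.64, 3.72, 2.06),
    ("Migraine", 14, 1.73, 1.02, 2.92, 1.72, 4.26, 1.72, 1.11, 0.79, -0.88),
    ("Throat tightness", 14, 7.56, 4.47, 12.79, 7.54, 79.26, 7.52, 4.85, 2.91, 1.24),
    ("Photophobia", 14, 9.26, 5.48, 15.66, 9.24, 102.50, 9.21, 5.93, 3.20, 1.54),
    ("Product after taste", 13, 59.67, 34.40, 103.51, 59.53, 730.54, 58.15, 36.68, 5.86, 4.19),
    ("Eye swelling", 13, 5.18, 3.00, 8.93, 5.17, 43.66, 5.16, 3.27, 2.37, 0.70),
    ("Fatigue", 13, 0.19, 0.11, 0.32, 0.19, 46.28, 0.19, 0.12, -2.41, -4.08),
    ("Dry mouth", 13, 2.29, 1.33, 3.95, 2.29, 9.42, 2.29, 1.45, 1.19, -0.47),
    ("Nasopharyngitis", 12, 0.68, 0.39, 1.21, 0.68, 1.75, 0.68, 0.43, -0.55, -2.21),
    ("Vertigo", 12, 3.02, 1.71, 5.32, 3.01, 16.15, 3.01, 1.87, 1.59, -0.08),
    ("Vomiting", 12, 0.36, 0.20, 0.63, 0.36, 13.76, 0.36, 0.22, -1.47, -3.14),
    ("Heart rate increased", 12, 1.51, 0.86, 2.66, 1.51, 2.05, 1.51, 0.94, 0.59, -1.07),
    ("Abdominal discomfort", 11, 0.73, 0.40, 1.31, 0.73, 1.12, 0.73, 0.44, -0.46, -2.12),
]

#: Pooled time-to-onset: n, median (IQR), mean, Weibull alpha/beta with 95% CIs.
TTO_REFERENCE = {
    "n": 125,
    "median": 7.0,
    "iqr": (2.0, 19.0),
    "mean": 29.3,
    "alpha": 16.73,
    "alpha_ci": (11.53, 21.92),
    "beta": 0.60,
    "beta_ci": (0.52, 0.67),
    "failure_type": "early",
}


def row_statistics(event: str):
    """Look up one published row (SOC first, then PT) as a DisproportionalityResult."""
    from .disprop import DisproportionalityResult

    for rows in (SOC_ROWS, PT_ROWS):
        for r in rows:
            if r[0].lower() == event.lower():
                return DisproportionalityResult(
                    event=r[0], a=r[1], ror=r[2], ror_lo=r[3], ror_hi=r[4],
                    prr=r[5], chi2=r[6], ebgm=r[7], ebgm05=r[8], ic=r[9], ic025=r[10],
                )
    raise KeyError(f"no published row for {event!r}")
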