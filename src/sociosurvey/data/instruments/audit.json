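{
  "id": "audit",
  "name": "AUDIT (Alcohol Use Disorders Identification Test)",
  "citation": "Babor, T.F., Higgins-Biddle, J.C., Saunders, J.B., Monteiro, M.G. The Alcohol Use Disorders Identification Test: Guidelines for Use in Primary Care. 2nd ed. World Health Organization, 2001.",
  "items": [
    {
      "id": "a1",
      "text": "How often do you have a drink containing alcohol?",
      "options": [
        {"code": "0", "label": "Never", "value": 0},
        {"code": "1", "label": "Monthly or less", "value": 1},
        {"code": "2", "label": "2-4 times a month", "value": 2},
        {"code": "3", "label": "2-3 times a week", "value": 3},
        {"code": "4", "label": "4 or more times a week", "value": 4}
      ]
    },
    {
      "id": "a2",
      "text": "How many drinks containing alcohol do you have on a typical day when you are drinking?",
      "options": [
        {"code": "0", "label": "1 or 2", "value": 0},
        {"code": "1", "label": "3 or 4", "value": 1},
        {"code": "2", "label": "5 or 6", "value": 2},
        {"code": "3", "label": "7 to 9", "value": 3},
        {"code": "4", "label": "10 or more", "value": 4}
      ]
    },
    {
      "id": "a3",
      "text": "How often do you have six or more drinks on one occasion?",
      "options": [
        {"code": "0", "label": "Never", "value": 0},
        {"code": "1", "label": "Less than monthly", "value": 1},
        {"code": "2", "label": "Monthly", "value": 2},
        {"code": "3", "label": "Weekly", "value": 3},
        {"code": "4", "label": "Daily or almost daily", "value": 4}
      ]
    },
    {
      "id": "a4",
      "text": "How often during the last year have you found that you were not able to stop drinking once you had started?",
      "options": [
        {"code": "0", "label": "Never", "value": 0},
        {"code": "1", "label": "Less than monthly", "value": 1},
        {"code": "2", "label": "Monthly", "value": 2},
        {"code": "3", "label": "Weekly", "value": 3},
        {"code": "4", "label": "Daily or almost daily", "value": 4}
      ]
    },
    {
      "id": "a5",
      "text": "How often during the last year have you failed to do what was normally expected from you because of drinking?",
      "options": [
        {"code": "0", "label": "Never", "value": 0},
        {"code": "1", "label": "Less than monthly", "value": 1},
        {"code": "2", "label": "Monthly", "value": 2},
        {"code": "3", "label": "Weekly", "value": 3},
        {"code": "4", "label": "Daily or almost daily", "value": 4}
      ]
    },
    {
      "id": "a6",
      "text": "How often during the last year have you needed a first drink in the morning to get yourself going after a heavy drinking session?",
      "options": [
        {"code": "0", "label": "Never", "value": 0},
        {"code": "1", "label": "Less than monthly", "value": 1},
        {"code": "2", "label": "Monthly", "value": 2},
        {"code": "3", "label": "Weekly", "value": 3},
        {"code": "4", "label": "Daily or almost daily", "value": 4}
      ]
    },
    {
      "id": "a7",
      "text": "How often during the last year have you had a feeling of guilt or remorse after drinking?",
      "options": [
        {"code": "0", "label": "Never", "value": 0},
        {"code": "1", "label": "Less than monthly", "value": 1},
        {"code": "2", "label": "Monthly", "value": 2},
        {"code": "3", "label": "Weekly", "value": 3},
        {"code": "4", "label": "Daily or almost daily", "value": 4}
      ]
    },
    {
      "id": "a8",
      "text": "How often during the last year have you been unable to remember what happened the night before because you had been drinking?",
      "options": [
        {"code": "0", "label": "Never", "value": 0},
        {"code": "1", "label": "Less than monthly", "value": 1},
        {"code": "2", "label": "Monthly", "value": 2},
        {"code": "3", "label": "Weekly", "value": 3},
        {"code": "4", "label": "Daily or almost daily", "value": 4}
      ]
    },
    {
      "id": "a9",
      "text": "Have you or someone else been injured as a result of your drinking?",
      "options": [
        {"code": "0", "label": "No", "value": 0},
        {"code": "2", "label": "Yes, but not in the last year", "value": 2},
        {"code": "4", "label": "Yes, during the last year", "value": 4}
      ]
    },
    {
      "id": "a10",
      "text": "Has a relative or friend or a doctor or another health worker been concerned about your drinking or suggested you cut down?",
      "options": [
        {"code": "0", "label": "No", "value": 0},
        {"code": "2", "label": "Yes, but not in the last year", "value": 2},
        {"code": "4", "label": "Yes, during the last year", "value": 4}
      ]
    }
  ],
  "scoring": {"expression": "sum(*)"},
  "bands": [
    {"label": "Zone I", "action": "Alcohol education", "lo": 0, "hi": 7},
    {"label": "Zone II", "action": "Simple advice", "lo": 8, "hi": 15},
    {"label": "Zone III", "action": "Simple advice plus brief counseling and continued monitoring", "lo": 16, "hi": 19},
    {"label": "Zone IV", "action": "Referral to specialist for diagnostic evaluation and treatment", "lo": 20, "hi": 40}
  ],
  "subscales": [],
  "provisional": false
}
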