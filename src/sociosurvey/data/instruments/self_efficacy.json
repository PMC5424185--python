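{
 "id": "self_efficacy",
 "name": "General Self-Efficacy Scale (Spanish adaptation, provisional definition)",
 "citation": "Baessler, J., Schwarzer, R. Evaluacion de la autoeficacia: adaptacion espanola de la Escala de Autoeficacia General. Ansiedad y Estres 2(1), 1996.",
 "items": [
  {
   "id": "s1",
   "text": "General self-efficacy statement 1 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s2",
   "text": "General self-efficacy statement 2 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s3",
   "text": "General self-efficacy statement 3 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s4",
   "text": "General self-efficacy statement 4 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s5",
   "text": "General self-efficacy statement 5 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s6",
   "text": "General self-efficacy statement 6 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s7",
   "text": "General self-efficacy statement 7 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s8",
   "text": "General self-efficacy statement 8 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s9",
   "text": "General self-efficacy statement 9 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  },
  {
   "id": "s10",
   "text": "General self-efficacy statement 10 (Spanish adaptation; provisional wording).",
   "options": [
    {
     "code": "1",
     "label": "not at all true",
     "value": 1
    },
    {
     "code": "2",
     "label": "hardly true",
     "value": 2
    },
    {
     "code": "3",
     "label": "moderately true",
     "value": 3
    },
    {
     "code": "4",
     "label": "exactly true",
     "value": 4
    }
   ]
  }
 ],
 "scoring": {
  "expression": "sum(*)"
 },
 "bands": [],
 "subscales": [],
 "provisional": true
}
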