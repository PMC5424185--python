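{
 "id": "estudes",
 "name": "ESTUDES substance-use indicators (provisional definition, alcohol items excluded)",
 "citation": "Plan Nacional sobre Drogas. Encuesta sobre Uso de Drogas en Ensenanzas Secundarias en Espana (ESTUDES). Ministerio de Sanidad, Spain.",
 "items": [
  {
   "id": "e1",
   "text": "How often have you smoked tobacco in the last 12 months?",
   "options": [
    {
     "code": "0",
     "label": "never",
     "value": 0
    },
    {
     "code": "1",
     "label": "once or twice",
     "value": 1
    },
    {
     "code": "2",
     "label": "monthly",
     "value": 2
    },
    {
     "code": "3",
     "label": "weekly",
     "value": 3
    },
    {
     "code": "4",
     "label": "daily or almost daily",
     "value": 4
    }
   ]
  },
  {
   "id": "e2",
   "text": "How often have you used cannabis in the last 12 months?",
   "options": [
    {
     "code": "0",
     "label": "never",
     "value": 0
    },
    {
     "code": "1",
     "label": "once or twice",
     "value": 1
    },
    {
     "code": "2",
     "label": "monthly",
     "value": 2
    },
    {
     "code": "3",
     "label": "weekly",
     "value": 3
    },
    {
     "code": "4",
     "label": "daily or almost daily",
     "value": 4
    }
   ]
  },
  {
   "id": "e3",
   "text": "How often have you used tranquilizers without prescription in the last 12 months?",
   "options": [
    {
     "code": "0",
     "label": "never",
     "value": 0
    },
    {
     "code": "1",
     "label": "once or twice",
     "value": 1
    },
    {
     "code": "2",
     "label": "monthly",
     "value": 2
    },
    {
     "code": "3",
     "label": "weekly",
     "value": 3
    },
    {
     "code": "4",
     "label": "daily or almost daily",
     "value": 4
    }
   ]
  },
  {
   "id": "e4",
   "text": "How often have you used any other illegal substance in the last 12 months?",
   "options": [
    {
     "code": "0",
     "label": "never",
     "value": 0
    },
    {
     "code": "1",
     "label": "once or twice",
     "value": 1
    },
    {
     "code": "2",
     "label": "monthly",
     "value": 2
    },
    {
     "code": "3",
     "label": "weekly",
     "value": 3
    },
    {
     "code": "4",
     "label": "daily or almost daily",
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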