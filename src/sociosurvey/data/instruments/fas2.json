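{
 "id": "fas2",
 "name": "FAS II (Family Affluence Scale II, provisional definition)",
 "citation": "Currie, C. et al. Researching health inequalities in adolescents: the development of the Health Behaviour in School-Aged Children (HBSC) Family Affluence Scale. Soc Sci Med 66(6), 2008.",
 "items": [
  {
   "id": "f1",
   "text": "Does your family own a car, van or truck?",
   "options": [
    {
     "code": "0",
     "label": "no",
     "value": 0
    },
    {
     "code": "1",
     "label": "yes, one",
     "value": 1
    },
    {
     "code": "2",
     "label": "yes, two or more",
     "value": 2
    }
   ]
  },
  {
   "id": "f2",
   "text": "Do you have your own bedroom for yourself?",
   "options": [
    {
     "code": "0",
     "label": "no",
     "value": 0
    },
    {
     "code": "1",
     "label": "yes",
     "value": 1
    }
   ]
  },
  {
   "id": "f3",
   "text": "During the past 12 months, how many times did you travel away on holiday with your family?",
   "options": [
    {
     "code": "0",
     "label": "not at all",
     "value": 0
    },
    {
     "code": "1",
     "label": "once",
     "value": 1
    },
    {
     "code": "2",
     "label": "twice",
     "value": 2
    },
    {
     "code": "3",
     "label": "more than twice",
     "value": 3
    }
   ]
  },
  {
   "id": "f4",
   "text": "How many computers does your family own?",
   "options": [
    {
     "code": "0",
     "label": "none",
     "value": 0
    },
    {
     "code": "1",
     "label": "one",
     "value": 1
    },
    {
     "code": "2",
     "label": "two",
     "value": 2
    },
    {
     "code": "3",
     "label": "more than two",
     "value": 3
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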