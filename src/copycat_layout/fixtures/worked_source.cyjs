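{
 "format_version": "1.0",
 "data": {
  "name": "worked-source"
 },
 "elements": {
  "nodes": [
   {
    "data": {
     "id": "1",
     "name": "A",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 0.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "2",
     "name": "B",
     "selected": false
    },
    "position": {
     "x": 120.0,
     "y": 0.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "3",
     "name": "C",
     "selected": false
    },
    "position": {
     "x": 240.0,
     "y": 0.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "4",
     "name": "D",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 120.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "5",
     "name": "E",
     "selected": false
    },
    "position": {
     "x": 120.0,
     "y": 120.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "6",
     "name": "F",
     "selected": false
    },
    "position": {
     "x": 240.0,
     "y": 120.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "7",
     "name": "G",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 240.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "8",
     "name": "H",
     "selected": false
    },
    "position": {
     "x": 120.0,
     "y": 240.0,
     "z": 0.0
    }
   }
  ],
  "edges": [
   {
    "data": {
     "source": "1",
     "target": "2",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "2",
     "target": "3",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "1",
     "target": "4",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "4",
     "target": "5",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "5",
     "target": "6",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "4",
     "target": "7",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "7",
     "target": "8",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "5",
     "target": "8",
     "interaction": "pp"
    }
   }
  ]
 }
}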