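"""Name pools for the synthetic registry generator.

The general surname list is sampled with a shallow power-law (many moderately
common names); the short-surname pool is sampled with a steep power-law and
overlaid on a configurable fraction of persons, emulating subpopulations in
which a handful of very short surnames (Lee, Kim, Li, ...) dominate and exact
name agreement carries little identifying information.

``PHONETIC_VARIANTS`` lists spelling classes whose members share a NYSIIS
code; the phonetic_swap corruption operator substitutes within a class, so a
corrupted surname still lands in the same NYSIIS block.
"""

SURNAMES = [
    "ABBOTT", "ABRAHAM", "ACOSTA", "ADAMS", "AGUILAR", "AHMED", "ALVAREZ",
    "ANDERSEN", "ANDERSON", "ANDREWS", "ANTONIOU", "ARMSTRONG", "ARNOLD",
    "ASHWORTH", "ATKINSON", "BAILEY", "BAKER", "BALDWIN", "BANERJEE",
    "BARNES", "BARRETT", "BAUTISTA", "BECKER", "BELANGER", "BENNETT",
    "BERGERON", "BHATTI", "BISHOP", "BLACKWOOD", "BOUCHARD", "BOWMAN",
    "BRADLEY", "BRENNAN", "BROOKS", "BROWN", "BRYANT", "BURGESS", "BURNS",
    "BUTLER", "CABRERA", "CAMERON", "CAMPBELL", "CARDOSO", "CARLSON",
    "CARPENTER", "CARROLL", "CARTER", "CASTILLO", "CHAMBERS", "CHANDLER",
    "CHAPMAN", "CHAUDHRY", "CHRISTENSEN", "CLARKE", "COLEMAN", "COLLINS",
    "CONNOLLY", "COOPER", "CORMIER", "COSTA", "CRAWFORD", "CUNNINGHAM",
    "CURTIS", "DASILVA", "DAVIDSON", "DAWSON", "DELACRUZ", "DESAI",
    "DESJARDINS", "DIALLO", "DICKSON", "DOHERTY", "DONNELLY", "DOUGLAS",
    "DRUMMOND", "DUBOIS", "DUNCAN", "EDWARDS", "ELLIOTT", "ESPOSITO",
    "EVANS", "FARRELL", "FERGUSON", "FERNANDES", "FERRARI", "FISCHER",
    "FITZGERALD", "FLEMING", "FLETCHER", "FLORES", "FONTAINE", "FORTIN",
    "FOSTER", "FRANKLIN", "FRASER", "FREEMAN", "GAGNON", "GALLAGHER",
    "GARCIA", "GARDINER", "GAUTHIER", "GIBSON", "GILBERT", "GOMEZ",
    "GONZALEZ", "GORDON", "GRAHAM", "GREENWOOD", "GREGORY", "GRIFFIN",
    "GUERRERO", "GUSTAFSON", "GUTIERREZ", "HAMILTON", "HANSEN", "HARDING",
    "HARPER", "HARRISON", "HASSAN", "HAWKINS", "HAYASHI", "HENDERSON",
    "HERNANDEZ", "HIGGINS", "HOFFMAN", "HOLLAND", "HOPKINS", "HORVATH",
    "HOWARD", "HUGHES", "HUSSAIN", "IBRAHIM", "IVANOV", "JACKSON",
    "JAMIESON", "JANSEN", "JARVIS", "JENSEN", "JIMENEZ", "JOHANSSON",
    "JOHNSTON", "KAPOOR", "KAMINSKI", "KAUFMAN", "KELLEHER", "KENNEDY",
    "KHALIL", "KOWALSKI", "KRISHNAN", "KUZNETSOV", "LAMBERT", "LANDRY",
    "LAVOIE", "LAWRENCE", "LAWSON", "LEBLANC", "LECLERC", "LEFEBVRE",
    "LESSARD", "LINDBERG", "LOMBARDI", "LOPEZ", "MAHMOOD", "MALHOTRA",
    "MALONE", "MARINO", "MARSHALL", "MARTINEZ", "MASSEY", "MATTHEWS",
    "MAXWELL", "MCALLISTER", "MCBRIDE", "MCCARTHY", "MCDONALD", "MCGREGOR",
    "MCINTYRE", "MCKENZIE", "MCLAUGHLIN", "MCLEOD", "MCMILLAN", "MCPHERSON",
    "MENDOZA", "MERCIER", "MEYER", "MILLER", "MITCHELL", "MOHAMED",
    "MONTGOMERY", "MORALES", "MOREAU", "MORGAN", "MORIN", "MORRISON",
    "MULLER", "MURPHY", "MURRAY", "NAKAMURA", "NAVARRO", "NELSON",
    "NICHOLSON", "NIELSEN", "NOVAK", "OBRIEN", "OCONNOR", "ODONNELL",
    "OKAFOR", "OLIVEIRA", "OLSEN", "ORTEGA", "OSBORNE", "OSULLIVAN",
    "PALMER", "PAQUETTE", "PARSONS", "PATTERSON", "PEARSON", "PELLETIER",
    "PEREIRA", "PETERSEN", "PETROV", "PHILLIPS", "POPESCU", "PORTER",
    "POULIN", "PRESTON", "QUINN", "RAHMAN", "RAMIREZ", "RASMUSSEN",
    "REYNOLDS", "RICHARDSON", "RILEY", "RIVERA", "ROBERTSON", "ROBINSON",
    "RODRIGUEZ", "ROMANO", "ROUSSEAU", "RUSSELL", "SAITO", "SANCHEZ",
    "SANDERS", "SANTOS", "SAUNDERS", "SCHNEIDER", "SCHOLZ", "SCHULTZ",
    "SHARMA", "SHEPHERD", "SHERIDAN", "SIMMONS", "SIMPSON", "SINCLAIR",
    "SOKOLOV", "SORENSEN", "SPENCER", "STEPHENS", "STEVENSON", "STEWART",
    "SULLIVAN", "SUTHERLAND", "SUZUKI", "TAKAHASHI", "TAVARES", "TAYLOR",
    "THERIAULT", "THOMPSON", "THORNTON", "TREMBLAY", "TURNER", "VARGAS",
    "VASILIEV", "VAZQUEZ", "VERMA", "VILLENEUVE", "WAGNER", "WALLACE",
    "WALTERS", "WATANABE", "WATSON", "WEBSTER", "WHEELER", "WHITFIELD",
    "WILKINSON", "WILLIAMSON", "WILSON", "WOODWARD", "WRIGHT", "YAMAMOTO",
    "YOSHIDA", "ZAHRA", "ZIELINSKI", "ZHANGWEI",
]

#: Default pool of very common short surnames (<= 4 letters).
SHORT_SURNAME_POOL = [
    "LEE", "LI", "KIM", "CHAN", "WONG", "CHEN", "LIU", "WANG", "NG", "PARK",
    "LIN", "CHO", "CHOI", "YANG", "ZHAO", "HO", "XU", "LAM", "TRAN", "NGO",
]

GIVEN_NAMES = [
    "AARON", "ADAM", "ADRIAN", "AGNES", "AHMAD", "AISHA", "ALAN", "ALBERT",
    "ALEXANDER", "ALICE", "AMANDA", "AMELIA", "ANDREA", "ANDREW", "ANGELA",
    "ANITA", "ANNA", "ANTHONY", "ANTONIO", "ARTHUR", "BARBARA", "BENJAMIN",
    "BRIAN", "BRUNO", "CARLOS", "CARMEN", "CAROLINE", "CATHERINE", "CECILIA",
    "CHARLES", "CHRISTINE", "CHRISTOPHER", "CLAIRE", "CLARA", "COLIN",
    "DANIEL", "DAVID", "DEBORAH", "DENNIS", "DIANA", "DMITRI", "DOMINIC",
    "DOROTHY", "DOUGLAS", "EDUARDO", "EDWARD", "ELENA", "ELIZABETH", "EMILY",
    "EMMA", "ERIC", "ESTHER", "EUGENE", "FARAH", "FATIMA", "FELIX",
    "FRANCES", "FRANCIS", "FRANK", "GABRIEL", "GEORGE", "GLORIA", "GRACE",
    "GREGORY", "HANNAH", "HAROLD", "HARRY", "HELEN", "HENRY", "HIROSHI",
    "IAN", "IRENE", "ISABEL", "IVAN", "JACK", "JACOB", "JAMES", "JANET",
    "JASON", "JEAN", "JENNIFER", "JESSICA", "JOHN", "JONATHAN", "JOSE",
    "JOSEPH", "JOYCE", "JUAN", "JULIA", "KAREN", "KATHLEEN", "KEITH",
    "KENNETH", "KEVIN", "LAILA", "LARRY", "LAURA", "LAWRENCE", "LEONARD",
    "LILIAN", "LINDA", "LOUIS", "LUCAS", "LUCY", "LUIS", "MARCO",
    "MARGARET", "MARIA", "MARIE", "MARTIN", "MARY", "MATTHEW", "MAYA",
    "MEHDI", "MICHAEL", "MICHELLE", "MING", "MOHAMMED", "MONICA", "NANCY",
    "NATALIA", "NATHAN", "NICHOLAS", "NICOLE", "NOOR", "OLGA", "OLIVER",
    "OMAR", "PABLO", "PATRICIA", "PATRICK", "PAUL", "PETER", "PHILIP",
    "PRIYA", "RACHEL", "RAYMOND", "REBECCA", "RICHARD", "ROBERT", "ROSA",
    "ROSE", "RUTH", "RYAN", "SAMUEL", "SANDRA", "SARAH", "SCOTT", "SEAN",
    "SHARON", "SIMON", "SOFIA", "STEPHEN", "SUSAN", "TERESA", "THOMAS",
    "TIMOTHY", "VICTOR", "VICTORIA", "VINCENT", "WALTER", "WEI", "WILLIAM",
    "XIAO", "YUKI", "YUSUF",
]

#: Spelling classes closed under NYSIIS (verified exhaustively in the tests).
PHONETIC_VARIANTS = [
    ["BROWN", "BRAUN"],
    ["MACDONALD", "MCDONALD"],
    ["PHILLIPS", "FILLIPS"],
    ["GREEN", "GREENE"],
    ["JOHNSON", "JONSON"],
    ["CLARK", "CLARKE"],
    ["LLOYD", "LOYD"],
    ["HANSEN", "HANSON"],
    ["NICHOLS", "NICOLS"],
    ["WONG", "WANG"],
    ["CHAN", "CHANN"],
    ["KIM", "KIMM"],
    ["PEDERSEN", "PEDERSON"],
    ["MULLER", "MUELLER"],
    ["REED", "READ"],
    ["STEWART", "STUART"],
]
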