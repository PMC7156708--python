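# SYNTHETIC fixture: surname frequency table in the shape of the 2010
# U.S. Census surname file (surname <TAB> count). Counts are invented;
# rows below the 100-count threshold exercise the build filter.
Smith	828230
Johnson	655520
Williams	539160
Brown	501260
Jones	498440
Garcia	394570
Miller	381560
Davis	358900
Rodriguez	322750
Martinez	318470
Hernandez	300070
Lopez	286850
Gonzalez	281350
Wilson	267240
Anderson	261780
Thomas	255220
Taylor	252250
Moore	239910
Jackson	236270
Martin	231630
Lee	230060
Perez	226840
Thompson	223110
White	220170
Harris	213290
Sanchez	212900
Clark	209610
Ramirez	205620
Lewis	204630
Robinson	200500
Walker	198900
Young	192260
Allen	190480
King	180570
Wright	179640
Scott	173290
Torres	172840
Nguyen	172540
Hill	168550
Flores	165330
Green	163050
Adams	156890
Nelson	155810
Baker	154460
Hall	150430
Rivera	148700
Campbell	148050
Mitchell	146500
Carter	144130
Roberts	141830
Gomez	140100
Phillips	137920
Evans	136050
Turner	133980
Diaz	133560
Parker	130450
Cruz	128650
Edwards	126740
Collins	125520
Reyes	124480
Stewart	123600
Morris	122490
Morales	121700
Murphy	120940
Cook	119920
Rogers	119220
Gutierrez	116320
Ortiz	115650
Morgan	114450
Cooper	113910
Peterson	112690
Bailey	111130
Reed	110580
Kelly	109630
Howard	107930
Ramos	107740
Kim	107470
Cox	105020
Ward	104160
Richardson	103540
Watson	100060
Brooks	99910
Chavez	98950
Wood	98220
James	97930
Bennett	97450
Gray	96920
Mendoza	96790
Ruiz	96600
Hughes	95790
Price	95420
Alvarez	95380
Castillo	94900
Sanders	94760
Patel	94040
Myers	93340
Long	92900
Ross	91990
Foster	91950
Jimenez	91360
Powell	90500
Jenkins	89610
Perry	89370
Russell	89010
Sullivan	88530
Bell	88040
Coleman	87240
Butler	86610
Henderson	86090
Barnes	85750
Fisher	85050
Vasquez	84500
Simmons	83780
Romero	83560
Jordan	83020
Patterson	82830
Alexander	82690
Hamilton	82670
Graham	82220
Reynolds	81610
Griffin	81340
Wallace	80960
Moreno	80440
West	80320
Cole	80130
Hayes	79910
Bryant	79460
Herrera	79150
Gibson	78810
Ellis	78360
Tran	78190
Medina	77800
Aguilar	77290
Stevens	76610
Murray	76350
Ford	75990
Castro	75950
Marshall	75630
Owens	75390
Harrison	74760
Fernandez	74370
Mcdonald	73990
Woods	73850
Washington	73260
Kennedy	73030
Wells	72640
Vargas	72380
Doe	54321
Snow	48200
Stone	47100
Winters	21500
Summers	20900
Banks	45300
Rice	44800
New	39800
Walks	2100
Knee	1800
Home	5400
Child	4900
Rarename	99
Vanishingly	12
Hapaxname	1
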