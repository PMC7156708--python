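# SYNTHETIC fixture: first-name-by-birth-year frequency table in the shape
# of the U.S. Social Security baby-name files (name <TAB> year <TAB> count).
# Counts are invented; rows below the 5-count threshold and outside the
# 1879-2017 year range exercise the build filter.
James	1950	86220
John	1950	79460
Robert	1950	83640
Michael	1960	85330
William	1950	60710
David	1955	78990
Richard	1950	52350
Joseph	1955	41040
Thomas	1952	43800
Charles	1950	41060
Christopher	1975	50180
Daniel	1975	41920
Matthew	1980	45680
Anthony	1980	24120
Mark	1960	37910
Donald	1940	33810
Steven	1958	32840
Paul	1955	25470
Andrew	1985	28470
Joshua	1985	38490
Kenneth	1945	25390
Kevin	1962	27060
Brian	1970	32380
George	1940	26470
Edward	1940	23380
Ronald	1945	26650
Timothy	1965	26480
Jason	1975	40750
Jeffrey	1962	28470
Ryan	1985	24900
Jacob	1995	34460
Gary	1950	28950
Nicholas	1990	26980
Eric	1972	25270
Jonathan	1980	23520
Stephen	1955	21480
Larry	1948	23660
Justin	1985	25170
Scott	1965	25120
Brandon	1990	23350
Benjamin	1990	17790
Samuel	1990	14190
Gregory	1960	21060
Frank	1935	21270
Alexander	1995	15390
Raymond	1940	17870
Patrick	1965	16480
Jack	1935	18390
Dennis	1948	18180
Jerry	1945	18960
Tyler	1992	23190
Aaron	1982	14090
Jose	1980	13650
Adam	1982	19100
Henry	1930	14690
Nathan	1990	13580
Douglas	1952	16580
Zachary	1992	15600
Peter	1955	12920
Kyle	1988	16520
Walter	1930	13340
Ethan	2000	17070
Jeremy	1978	15250
Harold	1930	12760
Keith	1960	12650
Christian	1995	13470
Roger	1945	13870
Noah	2005	15640
Gerald	1940	12320
Carl	1940	12010
Terry	1950	13060
Sean	1975	14230
Austin	1992	15550
Arthur	1930	11230
Lawrence	1940	10970
Jesse	1980	10920
Dylan	1995	14450
Bryan	1975	11730
Joe	1935	10360
Jordan	1990	13760
Billy	1945	11110
Bruce	1950	11180
Albert	1930	10190
Willie	1935	10930
Gabriel	1995	10390
Logan	2000	13080
Alan	1950	10240
Juan	1975	9550
Wayne	1945	10450
Roy	1935	9840
Ralph	1935	9340
Randy	1955	10840
Eugene	1935	9250
Vincent	1955	8550
Russell	1945	9280
Elijah	2005	10810
Louis	1930	8750
Bobby	1945	9480
Philip	1950	8240
Johnny	1945	9080
Mary	1950	62510
Patricia	1950	46960
Jennifer	1972	63600
Linda	1948	54970
Elizabeth	1955	35920
Barbara	1945	47940
Susan	1952	39250
Jessica	1985	46470
Sarah	1985	27570
Karen	1955	33160
Nancy	1950	32970
Lisa	1962	38960
Margaret	1940	29260
Betty	1935	30990
Sandra	1950	28210
Ashley	1985	26920
Dorothy	1930	28660
Kimberly	1968	27670
Emily	1995	25950
Donna	1952	27850
Michelle	1970	27310
Carol	1945	27400
Amanda	1982	25690
Melissa	1975	26270
Deborah	1952	26980
Stephanie	1975	22670
Rebecca	1970	20120
Sharon	1948	23590
Laura	1965	18760
Cynthia	1958	21910
Kathleen	1950	19610
Amy	1972	22640
Angela	1970	22120
Shirley	1935	22380
Anna	1990	14620
Brenda	1952	18550
Pamela	1952	19180
Emma	2002	16480
Nicole	1978	18340
Helen	1925	19940
Samantha	1990	17750
Katherine	1980	12480
Christine	1962	16760
Debra	1952	17590
Rachel	1982	15440
Catherine	1955	12840
Carolyn	1945	15000
Janet	1948	15310
Ruth	1925	16610
Maria	1965	12900
Heather	1975	18420
Diane	1950	14810
Virginia	1930	14900
Julie	1962	14580
Joyce	1940	15260
Victoria	1990	10980
Olivia	2002	13970
Kelly	1968	13940
Christina	1975	13000
Lauren	1988	13220
Joan	1938	13600
Evelyn	1925	12820
Judith	1942	13620
Megan	1985	13770
Cheryl	1952	13160
Andrea	1972	11680
Hannah	1995	13650
Martha	1935	12570
Jacqueline	1960	10870
Frances	1930	12500
Gloria	1940	11800
Ann	1945	12020
Teresa	1958	12250
Kathryn	1955	9830
Sara	1982	10810
Janice	1945	11490
Jean	1938	11630
Alice	1930	11490
Madison	2000	11270
Doris	1930	11250
Abigail	2000	10940
Julia	1990	8970
Judy	1945	11170
Grace	1995	9210
Denise	1958	10900
Amber	1982	10620
Marilyn	1940	10590
Beverly	1940	10540
Danielle	1980	9980
Theresa	1952	9860
Sophia	2005	10290
Marie	1935	9840
Diana	1958	9310
Brittany	1988	11130
Natalie	1992	8620
Isabella	2005	10120
Charlotte	1930	8550
Rose	1930	9010
Alexis	1995	9030
Kayla	1990	9800
Jane	1940	8870
June	1938	7990
April	1972	8110
May	1925	6130
Dawn	1962	9420
Crystal	1978	9060
Summer	1978	4200
Autumn	1985	4900
Zyqueth	1990	4
Xanthiq	1985	3
Obscurename	1870	9000
Futurename	2020	9000
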